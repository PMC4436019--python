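"""Order-of-magnitude markers (OOMM): dual-bar scientific-notation encoding.

A non-negative magnitude v is decomposed as A x 10^B with the digit A (a
real) shown on a narrow bar and the exponent B (an integer) on a wide bar,
both on linear 0-10 scales.  An expression level of 99 becomes 9.9 x 10^1:
wide bar 1, narrow bar 9.9.  The dual-bar form keeps both very large and
very small magnitudes readable at a glance.

Policy at the edges of the printed 0-10 scales (our choices): values in
(0, 1) keep B = 0 and A = v, since a negative exponent is not
representable on the scale; values at or beyond 10^11 saturate at
A = 10, B = 10 with an explicit flag rather than clamping silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["OOMMEncoding", "encode", "decode", "bar_lengths"]

MAX_EXPONENT = 10


@dataclass(frozen=True)
class OOMMEncoding:
    mantissa: float  # A, the digit: narrow bar, in [0, 10]
    exponent: int  # B: wide bar, in [0, 10]
    saturated: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.mantissa <= 10):
            raise ValueError(f"mantissa out of [0, 10]: {self.mantissa}")
        if not (0 <= self.exponent <= MAX_EXPONENT):
            raise ValueError(f"exponent out of [0, {MAX_EXPONENT}]: {self.exponent}")


def encode(v: float) -> OOMMEncoding:
    """Decompose v >= 0 into the (A, B) marker pair."""
    if not math.isfinite(v) or v < 0:
        raise ValueError(f"OOMM requires a finite non-negative value, got {v}")
    if v == 0:
        return OOMMEncoding(0.0, 0)
    if v < 1:
        return OOMMEncoding(v, 0)
    exponent = math.floor(math.log10(v))
    mantissa = v / 10.0**exponent
    # floating-point log10 can land one off at power boundaries
    if mantissa >= 10.0:
        exponent += 1
        mantissa /= 10.0
    elif mantissa < 1.0:
        exponent -= 1
        mantissa *= 10.0
    if exponent > MAX_EXPONENT:
        return OOMMEncoding(10.0, MAX_EXPONENT, saturated=True)
    return OOMMEncoding(mantissa, exponent)


def decode(e: OOMMEncoding) -> float:
    """Inverse of :func:`encode`; refuses saturated encodings (information lost)."""
    if e.saturated:
        raise ValueError("cannot decode a saturated OOMM encoding")
    return e.mantissa * 10.0**e.exponent


def bar_lengths(e: OOMMEncoding, unit: float = 1.0) -> tuple[float, float]:
    """(wide, narrow) bar lengths: exponent and digit scaled by ``unit``."""
    if not (unit > 0):
        raise ValueError(f"unit must be positive, got {unit}")
    return (e.exponent * unit, e.mantissa * unit)
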