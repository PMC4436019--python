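"""Radial sunburst layout and static SVG rendering.

Depth d of the hierarchy occupies the annulus between
``inner_radius + (d-1) * ring_width`` and ``inner_radius + d * ring_width``.
Roots partition the full circle proportionally to their leaf counts, and
every node's children partition the parent's angular interval the same
way, in lexicographic pathway-id order — equal angular weight per leaf
pathway keeps deep branches readable and the layout deterministic.

Angles are "clock" angles in radians: 0 is 12 o'clock and they grow
clockwise on screen.  Arc fill encodes either the three-way ortholog
status (green / yellow / purple for complete / partial / empty) or the
per-pathway DE ratio on a sequential white-to-red ramp.  OOMM dual bars
sit radially on the outer edge of an arc at its angular midpoint, and
crosstalk edges are drawn as chords between arc midpoints at the inner
radii.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Mapping

from matplotlib import colormaps
from matplotlib.colors import to_hex

from pathburst.crosstalk import CrosstalkEdge
from pathburst.model_io import PathwayHierarchy
from pathburst.oomm import OOMMEncoding, bar_lengths, encode
from pathburst.ortholog import OrthologProjection, OrthologStatus

logger = logging.getLogger(__name__)

__all__ = [
    "LayoutConfig",
    "SunburstArc",
    "ChordOverlay",
    "ColorMode",
    "STATUS_COLORS",
    "layout",
    "colorize",
    "attach_oomm",
    "crosstalk_overlay",
    "render_svg",
]

TWO_PI = 2.0 * math.pi

STATUS_COLORS: dict[OrthologStatus, str] = {
    OrthologStatus.COMPLETE: "#4daf4a",  # green
    OrthologStatus.PARTIAL: "#ffd92f",  # yellow
    OrthologStatus.EMPTY: "#984ea3",  # purple
}

UP_COLOR = "#ffd92f"  # up-expressed bar: yellow
DOWN_COLOR = "#377eb8"  # down-expressed bar: blue

_RAMP = colormaps["Reds"]


class ColorMode(enum.Enum):
    ORTHOLOG_STATUS = "status"
    DE_RATIO = "expression"


@dataclass(frozen=True)
class LayoutConfig:
    inner_radius: float = 60.0
    ring_width: float = 36.0
    max_depth: int | None = None
    start_angle: float = 0.0  # clock angle of the layout origin (0 = 12 o'clock)

    def __post_init__(self) -> None:
        if not (self.inner_radius > 0 and self.ring_width > 0):
            raise ValueError("inner_radius and ring_width must be positive")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class SunburstArc:
    pathway_id: str
    depth: int
    start_angle: float  # half-open interval [start_angle, end_angle)
    end_angle: float
    r_inner: float
    r_outer: float
    fill: str = "#cccccc"
    oomm: OOMMEncoding | None = None

    @property
    def span(self) -> float:
        return self.end_angle - self.start_angle

    @property
    def mid_angle(self) -> float:
        return 0.5 * (self.start_angle + self.end_angle)


@dataclass
class ChordOverlay:
    pathway_a: str
    pathway_b: str
    n_shared: int
    angle_a: float
    angle_b: float
    radius_a: float
    radius_b: float


def layout(
    h: PathwayHierarchy,
    cfg: LayoutConfig = LayoutConfig(),
    root: str | None = None,
) -> list[SunburstArc]:
    """Compute arcs for the forest (or the subtree under ``root``).

    Returned in pre-order; sibling intervals are disjoint half-open
    spans that exactly tile the parent's interval.
    """
    if root is not None and root not in h.nodes:
        raise KeyError(root)
    arcs: list[SunburstArc] = []
    tops = [root] if root is not None else list(h.roots)
    weights = [h.leaf_count(pid) for pid in tops]
    total = sum(weights)

    base_depth = h.depth(root) - 1 if root is not None else 0

    def recurse(pid: str, start: float, span: float) -> None:
        depth = h.depth(pid) - base_depth
        if cfg.max_depth is not None and depth > cfg.max_depth:
            return
        r_in = cfg.inner_radius + (depth - 1) * cfg.ring_width
        arcs.append(
            SunburstArc(
                pathway_id=pid,
                depth=depth,
                start_angle=start,
                end_angle=start + span,
                r_inner=r_in,
                r_outer=r_in + cfg.ring_width,
            )
        )
        kids = h.children(pid)
        if not kids:
            return
        kid_weights = [h.leaf_count(c) for c in kids]
        kid_total = sum(kid_weights)
        cursor = start
        for child, w in zip(kids, kid_weights):
            child_span = span * w / kid_total
            recurse(child, cursor, child_span)
            cursor += child_span

    cursor = cfg.start_angle
    for pid, w in zip(tops, weights):
        span = TWO_PI * w / total
        recurse(pid, cursor, span)
        cursor += span
    return arcs


def colorize(
    arcs: list[SunburstArc],
    data: OrthologProjection | Mapping[str, object],
    mode: ColorMode,
) -> list[SunburstArc]:
    """Assign arc fills from a projection (status mode) or summaries (DE mode)."""
    out = []
    for arc in arcs:
        if arc.pathway_id not in data:
            raise KeyError(arc.pathway_id)
        rec = data[arc.pathway_id]
        if mode is ColorMode.ORTHOLOG_STATUS:
            fill = STATUS_COLORS[rec.status]
        else:
            fill = to_hex(_RAMP(rec.de_ratio))
        out.append(replace_fill(arc, fill))
    return out


def replace_fill(arc: SunburstArc, fill: str) -> SunburstArc:
    return SunburstArc(
        pathway_id=arc.pathway_id,
        depth=arc.depth,
        start_angle=arc.start_angle,
        end_angle=arc.end_angle,
        r_inner=arc.r_inner,
        r_outer=arc.r_outer,
        fill=fill,
        oomm=arc.oomm,
    )


def attach_oomm(
    arcs: list[SunburstArc], values: Mapping[str, float]
) -> list[SunburstArc]:
    """Attach OOMM encodings for pathways with a value; others keep none."""
    out = []
    for arc in arcs:
        if arc.pathway_id in values:
            new = replace_fill(arc, arc.fill)
            new.oomm = encode(values[arc.pathway_id])
            out.append(new)
        else:
            out.append(arc)
    return out


def crosstalk_overlay(
    arcs: list[SunburstArc], edges: list[CrosstalkEdge]
) -> list[ChordOverlay]:
    """One chord per crosstalk edge, between arc angular midpoints.

    Edges whose endpoint pathway has no arc (pruned by max_depth) are
    skipped with a warning.
    """
    by_id = {a.pathway_id: a for a in arcs}
    chords = []
    for e in edges:
        a, b = by_id.get(e.pathway_a), by_id.get(e.pathway_b)
        if a is None or b is None:
            missing = e.pathway_a if a is None else e.pathway_b
            logger.warning("crosstalk edge endpoint %s has no arc; skipped", missing)
            continue
        chords.append(
            ChordOverlay(
                pathway_a=e.pathway_a,
                pathway_b=e.pathway_b,
                n_shared=e.n_shared,
                angle_a=a.mid_angle,
                angle_b=b.mid_angle,
                radius_a=a.r_inner,
                radius_b=b.r_inner,
            )
        )
    return chords


# -- SVG rendering -------------------------------------------------------


def _point(cx: float, cy: float, radius: float, clock_angle: float) -> tuple[float, float]:
    """Clock angle (0 at 12 o'clock, clockwise) to SVG coordinates (y down)."""
    return (cx + radius * math.sin(clock_angle), cy - radius * math.cos(clock_angle))


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _sector_path(
    cx: float, cy: float, arc: SunburstArc
) -> str:
    """SVG path data for an annular sector."""
    a0, a1 = arc.start_angle, arc.end_angle
    large = 1 if (a1 - a0) % TWO_PI > math.pi else 0
    x0, y0 = _point(cx, cy, arc.r_inner, a0)
    x1, y1 = _point(cx, cy, arc.r_outer, a0)
    x2, y2 = _point(cx, cy, arc.r_outer, a1)
    x3, y3 = _point(cx, cy, arc.r_inner, a1)
    # clockwise clock angles are sweep=1 in SVG screen coordinates
    return (
        f"M {_fmt(x0)} {_fmt(y0)} "
        f"L {_fmt(x1)} {_fmt(y1)} "
        f"A {_fmt(arc.r_outer)} {_fmt(arc.r_outer)} 0 {large} 1 {_fmt(x2)} {_fmt(y2)} "
        f"L {_fmt(x3)} {_fmt(y3)} "
        f"A {_fmt(arc.r_inner)} {_fmt(arc.r_inner)} 0 {large} 0 {_fmt(x0)} {_fmt(y0)} Z"
    )


def _oomm_bars(
    cx: float, cy: float, arc: SunburstArc, unit: float
) -> list[str]:
    """Paired radial rectangles (wide exponent, narrow digit) at the arc midpoint."""
    wide_len, narrow_len = bar_lengths(arc.oomm, unit)
    angle_deg = math.degrees(arc.mid_angle)
    bx, by = _point(cx, cy, arc.r_outer, arc.mid_angle)
    elems = []
    for offset, width, length, cls in (
        (-4.5, 4.0, wide_len, "oomm-wide"),
        (0.5, 2.0, narrow_len, "oomm-narrow"),
    ):
        elems.append(
            f'<rect class="{cls}" x="{_fmt(offset)}" y="{_fmt(-length)}" '
            f'width="{_fmt(width)}" height="{_fmt(length)}" '
            f'transform="translate({_fmt(bx)},{_fmt(by)}) rotate({_fmt(angle_deg)})"/>'
        )
    return elems


def render_svg(
    arcs: list[SunburstArc],
    overlays: list[ChordOverlay] | None = None,
    path: str | None = None,
    oomm_unit: float = 2.0,
) -> str:
    """Render arcs (plus optional chord overlays) to an SVG 1.1 document.

    Output is deterministic for a fixed input: element order follows the
    arc list, then the overlay list.  Returns the SVG text and, when
    ``path`` is given, also writes it there.
    """
    if not arcs:
        raise ValueError("cannot render an empty arc list")
    r_max = max(a.r_outer for a in arcs) + 12 * oomm_unit
    size = 2.0 * r_max
    cx = cy = r_max

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(size)}" height="{_fmt(size)}" '
        f'viewBox="0 0 {_fmt(size)} {_fmt(size)}">',
        "<style>"
        ".arc{stroke:#ffffff;stroke-width:1}"
        ".chord{stroke:#666666;fill:none;opacity:0.6}"
        ".oomm-wide{fill:#555555}"
        ".oomm-narrow{fill:#d95f02}"
        "</style>",
        '<g class="arcs">',
    ]
    for arc in arcs:
        parts.append(
            f'<path class="arc" id="arc-{arc.pathway_id}" fill="{arc.fill}" '
            f'd="{_sector_path(cx, cy, arc)}"/>'
        )
    parts.append("</g>")

    bar_elems = []
    for arc in arcs:
        if arc.oomm is not None:
            bar_elems.extend(_oomm_bars(cx, cy, arc, oomm_unit))
    if bar_elems:
        parts.append('<g class="oomm">')
        parts.extend(bar_elems)
        parts.append("</g>")

    if overlays:
        parts.append('<g class="chords">')
        for ch in overlays:
            xa, ya = _point(cx, cy, ch.radius_a, ch.angle_a)
            xb, yb = _point(cx, cy, ch.radius_b, ch.angle_b)
            width = 0.75 + 0.5 * math.log10(1 + ch.n_shared)
            parts.append(
                f'<path class="chord" stroke-width="{_fmt(width)}" '
                f'd="M {_fmt(xa)} {_fmt(ya)} Q {_fmt(cx)} {_fmt(cy)} '
                f'{_fmt(xb)} {_fmt(yb)}">'
                f"<title>{ch.pathway_a}-{ch.pathway_b}: {ch.n_shared}</title></path>"
            )
        parts.append("</g>")

    parts.append("</svg>")
    doc = "\n".join(parts) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(doc)
    return doc
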