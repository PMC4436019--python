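"""Differential-expression overlay on the projected hierarchy.

Input is a headered TSV of (entrez, symbol, log2_ratio), the ratio being a
log2 fold change between two biological states.  A gene is UP when its
ratio is at or above the cutoff, DOWN at or below minus the cutoff
(boundary inclusive), UNCHANGED otherwise; the default cutoff of 1.0
corresponds to a 2-fold change.

Per pathway, records are matched against the pathway's *orthologous* gene
set (Entrez number first when both sides carry one, gene symbol otherwise)
and summarized as the DE ratio

    de_ratio = (n_up + n_down) / n_ortho

— the fraction of the pathway's orthologous proteins that are
differentially expressed, which is always in [0, 1] and drives the
sunburst color ramp.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import IO, TYPE_CHECKING, Iterable

from pathburst.model_io import GeneID, ParseError, PathwayHierarchy
from pathburst.ortholog import (
    OrthologMap,
    OrthologProjection,
    n_products,
    orthologous_genes,
)

if TYPE_CHECKING:
    from pathburst.crosstalk import CrosstalkIndex

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionRecord",
    "ExpressionConfig",
    "DEStatus",
    "PathwayExpressionSummary",
    "GeneTableRow",
    "parse_expression",
    "classify_de",
    "summarize_pathway",
    "summarize_all",
    "gene_table",
]

DEFAULT_CUTOFF = 1.0  # |log2 ratio| >= 1, i.e. 2-fold change


@dataclass(frozen=True)
class ExpressionRecord:
    gene: GeneID
    log2_ratio: float


@dataclass(frozen=True)
class ExpressionConfig:
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if not (self.cutoff > 0):
            raise ValueError(f"cutoff must be > 0, got {self.cutoff}")


class DEStatus(enum.Enum):
    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"


@dataclass
class PathwayExpressionSummary:
    pathway_id: str
    n_up: int
    n_down: int
    n_ortho: int

    @property
    def de_ratio(self) -> float:
        if self.n_ortho == 0:
            return 0.0
        return (self.n_up + self.n_down) / self.n_ortho


@dataclass
class GeneTableRow:
    entrez: int | None
    symbol: str
    n_products: int
    log2_ratio: float
    status: DEStatus
    n_crosstalk_pathways: int
    rate_limiting: bool


def parse_expression(
    stream: IO[str] | Iterable[str] | str, linear_ratio: bool = False
) -> list[ExpressionRecord]:
    """Read the expression TSV; drop (and log) rows with unusable ratios.

    Duplicate records for one gene keep the largest |log2_ratio|.  With
    ``linear_ratio`` the ratio column holds linear fold changes and log2
    is applied on load.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()
    lines = iter(stream)
    try:
        header = next(lines).rstrip("\r\n").split("\t")
    except StopIteration:
        raise ParseError("expression table is empty (no header)")
    cols = [c.strip().lower() for c in header]
    for required in ("entrez", "symbol", "log2_ratio"):
        if required not in cols:
            raise ParseError(f"expression table is missing column {required!r}")
    i_entrez, i_symbol, i_ratio = (
        cols.index("entrez"),
        cols.index("symbol"),
        cols.index("log2_ratio"),
    )

    by_gene: dict[GeneID, ExpressionRecord] = {}
    n_dropped = 0
    for lineno, raw in enumerate(lines, start=2):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) <= max(i_entrez, i_symbol, i_ratio):
            n_dropped += 1
            continue
        symbol = fields[i_symbol].strip()
        if not symbol:
            n_dropped += 1
            continue
        entrez_txt = fields[i_entrez].strip()
        entrez = int(entrez_txt) if entrez_txt else None
        try:
            ratio = float(fields[i_ratio])
        except ValueError:
            n_dropped += 1
            continue
        if not math.isfinite(ratio):
            n_dropped += 1
            continue
        if linear_ratio:
            if ratio <= 0:
                n_dropped += 1
                continue
            ratio = math.log2(ratio)
        gene = GeneID(symbol, entrez)
        prev = by_gene.get(gene)
        if prev is not None:
            logger.warning(
                "duplicate expression record for %s; keeping larger |log2_ratio|",
                gene.symbol,
            )
            if abs(ratio) <= abs(prev.log2_ratio):
                continue
        by_gene[gene] = ExpressionRecord(gene, ratio)
    if n_dropped:
        logger.warning("dropped %d expression rows with missing/non-finite ratio", n_dropped)
    return list(by_gene.values())


def classify_de(r: ExpressionRecord, cfg: ExpressionConfig) -> DEStatus:
    """UP / DOWN / UNCHANGED at the cutoff; the boundary counts as DE."""
    if r.log2_ratio >= cfg.cutoff:
        return DEStatus.UP
    if r.log2_ratio <= -cfg.cutoff:
        return DEStatus.DOWN
    return DEStatus.UNCHANGED


def _match_records(
    genes: set[GeneID], records: list[ExpressionRecord]
) -> dict[GeneID, ExpressionRecord]:
    """Match records to a gene set: Entrez number first, symbol fallback.

    Returns at most one record per pathway gene.
    """
    by_entrez = {g.entrez: g for g in genes if g.entrez is not None}
    by_symbol = {g.symbol: g for g in genes}
    matched: dict[GeneID, ExpressionRecord] = {}
    for rec in records:
        target = None
        if rec.gene.entrez is not None and rec.gene.entrez in by_entrez:
            target = by_entrez[rec.gene.entrez]
        elif rec.gene.symbol in by_symbol:
            target = by_symbol[rec.gene.symbol]
        if target is None:
            continue
        prev = matched.get(target)
        if prev is None or abs(rec.log2_ratio) > abs(prev.log2_ratio):
            matched[target] = rec
    return matched


def summarize_pathway(
    h: PathwayHierarchy,
    pathway_id: str,
    records: list[ExpressionRecord],
    proj: OrthologProjection,
    cfg: ExpressionConfig,
    m: OrthologMap,
) -> PathwayExpressionSummary:
    """Count UP/DOWN among records matched to the pathway's orthologous genes."""
    if pathway_id not in h.nodes:
        raise KeyError(pathway_id)
    ortho = orthologous_genes(h, pathway_id, m)
    matched = _match_records(ortho, records)
    n_up = n_down = 0
    for rec in matched.values():
        status = classify_de(rec, cfg)
        if status is DEStatus.UP:
            n_up += 1
        elif status is DEStatus.DOWN:
            n_down += 1
    return PathwayExpressionSummary(
        pathway_id=pathway_id,
        n_up=n_up,
        n_down=n_down,
        n_ortho=proj[pathway_id].n_ortho,
    )


def summarize_all(
    h: PathwayHierarchy,
    records: list[ExpressionRecord],
    proj: OrthologProjection,
    cfg: ExpressionConfig,
    m: OrthologMap,
) -> dict[str, PathwayExpressionSummary]:
    return {
        pid: summarize_pathway(h, pid, records, proj, cfg, m) for pid in h.nodes
    }


def gene_table(
    h: PathwayHierarchy,
    pathway_id: str,
    records: list[ExpressionRecord],
    proj: OrthologProjection,
    idx: "CrosstalkIndex | None",
    rate_limiting: dict[GeneID, bool] | None,
    cfg: ExpressionConfig,
    m: OrthologMap,
) -> list[GeneTableRow]:
    """Per-gene detail table for one pathway: one row per matched orthologous gene."""
    from pathburst.crosstalk import crosstalk_count

    if pathway_id not in h.nodes:
        raise KeyError(pathway_id)
    rate_limiting = rate_limiting or {}
    ortho = orthologous_genes(h, pathway_id, m)
    matched = _match_records(ortho, records)
    rows = []
    for gene in sorted(matched, key=lambda g: g.symbol):
        rec = matched[gene]
        rows.append(
            GeneTableRow(
                entrez=rec.gene.entrez if rec.gene.entrez is not None else gene.entrez,
                symbol=gene.symbol,
                n_products=n_products(h, pathway_id, gene),
                log2_ratio=rec.log2_ratio,
                status=classify_de(rec, cfg),
                n_crosstalk_pathways=crosstalk_count(idx, gene) if idx else 0,
                rate_limiting=rate_limiting.get(gene, False),
            )
        )
    return rows


def write_summary_report(
    h: PathwayHierarchy,
    summaries: dict[str, PathwayExpressionSummary],
    stream: IO[str],
) -> None:
    stream.write("pathway_id\tn_up\tn_down\tn_ortho\tde_ratio\n")
    for pid in h.walk():
        s = summaries[pid]
        stream.write(
            f"{pid}\t{s.n_up}\t{s.n_down}\t{s.n_ortho}\t{s.de_ratio:.6f}\n"
        )


def write_gene_table(rows: list[GeneTableRow], stream: IO[str]) -> None:
    stream.write(
        "entrez\tsymbol\tn_products\tlog2_ratio\tstatus\t"
        "n_crosstalk_pathways\trate_limiting\n"
    )
    for r in rows:
        entrez = "" if r.entrez is None else str(r.entrez)
        stream.write(
            f"{entrez}\t{r.symbol}\t{r.n_products}\t{r.log2_ratio:.6f}\t"
            f"{r.status.value}\t{r.n_crosstalk_pathways}\t{int(r.rate_limiting)}\n"
        )
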