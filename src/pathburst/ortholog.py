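"""Cross-species projection of the pathway hierarchy via an ortholog map.

Each pathway of the reference hierarchy is classified for a target species:

* ``COMPLETE`` — every gene of the pathway has an ortholog in the target;
* ``PARTIAL``  — some but not all genes have orthologs;
* ``EMPTY``    — no gene of the pathway has an ortholog.

Presence is evaluated on the reference side (a reference gene either has
at least one target ortholog or it does not); the multiplicity of target
orthologs does not change the status.  Pathways with no genes at all are
reported EMPTY with a distinguishing flag, since the three-way definition
presumes a non-empty gene set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import IO, TYPE_CHECKING, Iterable

from pathburst.model_io import GeneID, ParseError, PathwayHierarchy, _lines

if TYPE_CHECKING:
    from pathburst.crosstalk import CrosstalkIndex

__all__ = [
    "OrthologMap",
    "OrthologStatus",
    "OrthologProjection",
    "OrthologTableRow",
    "parse_ortholog_map",
    "classify",
    "project",
    "ortholog_table",
    "sort_table",
]


class OrthologStatus(enum.Enum):
    COMPLETE = "complete"
    PARTIAL = "partial"
    EMPTY = "empty"


@dataclass
class OrthologMap:
    """Many-to-many reference-gene → target-gene ortholog pairs."""

    species_pair: tuple[str, str]
    pairs: set[tuple[GeneID, GeneID]] = field(default_factory=set)

    def reference_genes(self) -> set[GeneID]:
        return {ref for ref, _ in self.pairs}


@dataclass
class PathwayOrthology:
    """Per-pathway projection record."""

    status: OrthologStatus
    n_genes: int
    n_ortho: int
    gene_less: bool = False

    def __post_init__(self) -> None:
        assert 0 <= self.n_ortho <= self.n_genes


OrthologProjection = dict[str, PathwayOrthology]


@dataclass
class OrthologTableRow:
    gene: GeneID
    n_products: int
    n_crosstalk_pathways: int
    rate_limiting: bool


def parse_ortholog_map(
    stream: IO[str] | Iterable[str] | str,
    reference_name: str = "reference",
    target_name: str = "target",
) -> OrthologMap:
    """Read a 2-column TSV of (reference symbol, target symbol) pairs."""
    pairs: set[tuple[GeneID, GeneID]] = set()
    for lineno, line in _lines(stream):
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        pairs.add((GeneID(fields[0]), GeneID(fields[1])))
    return OrthologMap(species_pair=(reference_name, target_name), pairs=pairs)


def classify(genes: set[GeneID], m: OrthologMap) -> OrthologStatus:
    """Three-way ortholog status of a gene set under a map.

    COMPLETE if every gene has an ortholog (and the set is non-empty),
    EMPTY if none does (including the degenerate empty set), PARTIAL
    otherwise.
    """
    mapped = m.reference_genes()
    if not genes or not (genes & mapped):
        return OrthologStatus.EMPTY
    if genes <= mapped:
        return OrthologStatus.COMPLETE
    return OrthologStatus.PARTIAL


def project(h: PathwayHierarchy, m: OrthologMap) -> OrthologProjection:
    """Classify every pathway and count its (orthologous) subtree genes."""
    mapped = m.reference_genes()
    proj: OrthologProjection = {}
    for pid in h.nodes:
        genes = h.subtree_genes(pid)
        proj[pid] = PathwayOrthology(
            status=classify(genes, m),
            n_genes=len(genes),
            n_ortho=len(genes & mapped),
            gene_less=not genes,
        )
    return proj


def orthologous_genes(
    h: PathwayHierarchy, pathway_id: str, m: OrthologMap
) -> set[GeneID]:
    """The pathway's subtree genes that have a target ortholog.

    Keeps the pathway-side GeneID objects (which may carry Entrez numbers
    the map lacks) rather than the map-side ones.
    """
    mapped = m.reference_genes()
    return {g for g in h.subtree_genes(pathway_id) if g in mapped}


def n_products(h: PathwayHierarchy, pathway_id: str, gene: GeneID) -> int:
    """Gene-product count of a gene within a pathway.

    Counted as the number of leaf sub-pathways under ``pathway_id`` whose
    gene set contains the gene — each leaf pathway occurrence is treated
    as one product context.
    """
    n = 0
    for pid in h.walk(pathway_id):
        if not h.children(pid) and gene in h.subtree_genes(pid):
            n += 1
    return n


def ortholog_table(
    h: PathwayHierarchy,
    pathway_id: str,
    m: OrthologMap,
    xidx: "CrosstalkIndex | None" = None,
    rate_limiting: dict[GeneID, bool] | None = None,
) -> list[OrthologTableRow]:
    """One row per orthologous gene of the pathway, sorted by symbol."""
    from pathburst.crosstalk import crosstalk_count

    if pathway_id not in h.nodes:
        raise KeyError(pathway_id)
    rate_limiting = rate_limiting or {}
    ortho = orthologous_genes(h, pathway_id, m)
    rows = []
    for gene in sorted(ortho, key=lambda g: g.symbol):
        rows.append(
            OrthologTableRow(
                gene=gene,
                n_products=n_products(h, pathway_id, gene),
                n_crosstalk_pathways=crosstalk_count(xidx, gene) if xidx else 0,
                rate_limiting=rate_limiting.get(gene, False),
            )
        )
    return rows


def sort_table(
    rows: list[OrthologTableRow], column: str, descending: bool = False
) -> list[OrthologTableRow]:
    """Stable re-sort of a table by one column; symbols compare case-insensitively."""
    if column == "gene":
        key = lambda r: r.gene.symbol.upper()
    elif column in ("n_products", "n_crosstalk_pathways", "rate_limiting"):
        key = lambda r: getattr(r, column)
    else:
        raise ValueError(f"unknown column {column!r}")
    return sorted(rows, key=key, reverse=descending)


def parse_rate_limiting(
    stream: IO[str] | Iterable[str] | str,
) -> dict[GeneID, bool]:
    """Read the rate-limiting annotation: TSV of (symbol, 0/1)."""
    flags: dict[GeneID, bool] = {}
    for lineno, line in _lines(stream):
        fields = line.split("\t")
        if len(fields) != 2 or fields[1].strip() not in ("0", "1"):
            raise ParseError(
                f"line {lineno}: expected 'symbol<TAB>0|1', got {line!r}"
            )
        flags[GeneID(fields[0])] = fields[1].strip() == "1"
    return flags


def write_projection_report(
    h: PathwayHierarchy, proj: OrthologProjection, stream: IO[str]
) -> None:
    """Per-pathway status report TSV, in layout order."""
    stream.write("pathway_id\tname\tdepth\tn_genes\tn_ortho\tstatus\n")
    for pid in h.walk():
        rec = proj[pid]
        stream.write(
            f"{pid}\t{h.nodes[pid].name}\t{h.depth(pid)}\t"
            f"{rec.n_genes}\t{rec.n_ortho}\t{rec.status.value}\n"
        )
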