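"""Crosstalk: gene products shared between pathways at one hierarchy level.

A cross-talking gene product belongs to two or more pathways at the chosen
level (default level 2, the second ring); each unordered pathway pair
sharing at least one gene gets a crosstalk edge weighted by the shared-gene
count.  Only same-level pathways are compared — in a tree, the pathways of
one level have disjoint subtrees, so a gene shared between two of them is
a genuine interconnection, not nesting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

from pathburst.model_io import GeneID, PathwayHierarchy

__all__ = [
    "CrosstalkIndex",
    "CrosstalkEdge",
    "build_index",
    "crosstalk_genes",
    "crosstalk_edges",
    "crosstalk_count",
    "highlight_targets",
]


@dataclass
class CrosstalkIndex:
    level: int
    membership: dict[GeneID, set[str]] = field(default_factory=dict)


@dataclass
class CrosstalkEdge:
    pathway_a: str
    pathway_b: str
    shared_genes: set[GeneID]

    def __post_init__(self) -> None:
        if self.pathway_a > self.pathway_b:
            self.pathway_a, self.pathway_b = self.pathway_b, self.pathway_a

    @property
    def n_shared(self) -> int:
        return len(self.shared_genes)


def build_index(h: PathwayHierarchy, level: int = 2) -> CrosstalkIndex:
    """Map each gene to the set of level-``level`` pathways whose subtree holds it."""
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    membership: dict[GeneID, set[str]] = {}
    for pid in h.nodes_at_depth(level):
        for gene in h.subtree_genes(pid):
            membership.setdefault(gene, set()).add(pid)
    return CrosstalkIndex(level=level, membership=membership)


def crosstalk_genes(idx: CrosstalkIndex) -> set[GeneID]:
    """Genes belonging to two or more pathways at the index level."""
    return {g for g, paths in idx.membership.items() if len(paths) >= 2}


def crosstalk_edges(idx: CrosstalkIndex) -> list[CrosstalkEdge]:
    """One edge per unordered pathway pair with >=1 shared gene, sorted."""
    shared: dict[tuple[str, str], set[GeneID]] = {}
    for gene, paths in idx.membership.items():
        if len(paths) < 2:
            continue
        ordered = sorted(paths)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                shared.setdefault((a, b), set()).add(gene)
    return [
        CrosstalkEdge(a, b, genes) for (a, b), genes in sorted(shared.items())
    ]


def crosstalk_count(idx: CrosstalkIndex, gene: GeneID) -> int:
    """Number of pathways influenced through crosstalk: |membership| if >=2, else 0."""
    paths = idx.membership.get(gene, set())
    return len(paths) if len(paths) >= 2 else 0


def highlight_targets(idx: CrosstalkIndex, gene: GeneID) -> set[str]:
    """Pathways to highlight for a cross-talking gene; empty if not cross-talking."""
    paths = idx.membership.get(gene, set())
    return set(paths) if len(paths) >= 2 else set()


def write_crosstalk_report(edges: list[CrosstalkEdge], stream: IO[str]) -> None:
    stream.write("pathway_a\tpathway_b\tn_shared\tshared_genes\n")
    for e in edges:
        symbols = ";".join(sorted(g.symbol for g in e.shared_genes))
        stream.write(f"{e.pathway_a}\t{e.pathway_b}\t{e.n_shared}\t{symbols}\n")
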