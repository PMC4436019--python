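"""Deterministic synthetic inputs: hierarchies, ortholog maps, expression tables.

Every module of the package is exercised end-to-end without any download:
the generators emit the exact text dialects the parsers read (relations
TSV, GMT, ortholog TSV, expression TSV, rate-limiting TSV), so generated
streams always parse cleanly.  One integer seed drives a single
pseudo-random stream per generator call and reruns are bit-stable.

The generated world is a complete b-ary pathway forest: only leaves carry
genes directly (internal pathways inherit the union of their subtrees,
mirroring how a parent pathway aggregates its sub-pathways).  Crosstalk is
induced by inserting a fraction of all genes into a second, randomly
chosen leaf.  Ortholog coverage and the differentially expressed fraction
are independent Bernoulli draws per gene, so recovery of those rates is
binomial by construction.

Gene symbols are synthetic tokens (G000001, ...) with fabricated Entrez
IDs in a reserved high range (900000001, ...) that cannot collide with
real identifiers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from pathburst.model_io import GeneID, PathwayHierarchy, build_hierarchy, parse_gmt, parse_relations
from pathburst.ortholog import OrthologMap, parse_ortholog_map

__all__ = [
    "GenParams",
    "gen_hierarchy",
    "gen_ortholog_map",
    "gen_expression",
    "gen_rate_limiting",
]

ENTREZ_BASE = 900_000_000


@dataclass(frozen=True)
class GenParams:
    seed: int = 0
    n_roots: int = 3
    depth: int = 3
    branching: int = 3
    genes_per_leaf: int = 8
    crosstalk_fraction: float = 0.1
    ortho_coverage: float = 0.8
    frac_de: float = 0.3
    de_effect: float = 3.0

    def __post_init__(self) -> None:
        if self.n_roots < 1 or self.depth < 1 or self.branching < 1:
            raise ValueError("n_roots, depth and branching must be >= 1")
        if self.genes_per_leaf < 0:
            raise ValueError("genes_per_leaf must be >= 0")
        for name in ("crosstalk_fraction", "ortho_coverage", "frac_de"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (self.de_effect > 0):
            raise ValueError("de_effect must be positive")


def _symbol(i: int) -> str:
    return f"G{i:06d}"


def gen_hierarchy(p: GenParams) -> tuple[PathwayHierarchy, str, str]:
    """Generate a complete b-ary forest; returns (hierarchy, relations TSV, GMT).

    Pathway ids encode the tree position (R01, R01.1, R01.1.2, ...) so the
    lexicographic sibling order is also the generation order.  Leaves get
    ``genes_per_leaf`` unique genes each; then ``crosstalk_fraction`` of
    all genes are inserted into a second random leaf.
    """
    rng = np.random.default_rng(p.seed)
    edges: list[tuple[str, str]] = []
    leaves: list[str] = []

    def grow(node_id: str, level: int) -> None:
        if level == p.depth:
            leaves.append(node_id)
            return
        for i in range(1, p.branching + 1):
            child = f"{node_id}.{i}"
            edges.append((node_id, child))
            grow(child, level + 1)

    for r in range(1, p.n_roots + 1):
        grow(f"R{r:02d}", 1)

    gene_sets: dict[str, set[GeneID]] = {leaf: set() for leaf in leaves}
    all_genes: list[GeneID] = []
    counter = 1
    for leaf in leaves:
        for _ in range(p.genes_per_leaf):
            g = GeneID(_symbol(counter), ENTREZ_BASE + counter)
            counter += 1
            gene_sets[leaf].add(g)
            all_genes.append(g)

    home = {g: leaf for leaf in leaves for g in gene_sets[leaf]}
    if len(leaves) >= 2 and p.crosstalk_fraction > 0 and all_genes:
        n_cross = int(round(p.crosstalk_fraction * len(all_genes)))
        picked = rng.choice(len(all_genes), size=n_cross, replace=False)
        for idx in sorted(picked):
            g = all_genes[idx]
            others = [l for l in leaves if l != home[g]]
            second = others[rng.integers(len(others))]
            gene_sets[second].add(g)

    relations = "# parent\tchild\n" + "".join(f"{a}\t{b}\n" for a, b in edges)
    gmt_lines = []
    for leaf in leaves:
        symbols = "\t".join(sorted(g.symbol for g in gene_sets[leaf]))
        tail = f"\t{symbols}" if symbols else ""
        gmt_lines.append(f"{leaf}\tsynthetic leaf pathway{tail}\n")
    gmt = "".join(gmt_lines)

    entrez = {g.symbol: g.entrez for g in all_genes}
    gene_sets_parsed = {
        pid: {GeneID(g.symbol, entrez[g.symbol]) for g in genes}
        for pid, genes in parse_gmt(io.StringIO(gmt)).items()
    }
    h = build_hierarchy(parse_relations(io.StringIO(relations)), gene_sets_parsed)
    return h, relations, gmt


def gen_ortholog_map(
    h: PathwayHierarchy, coverage: float, seed: int
) -> tuple[OrthologMap, str]:
    """Bernoulli(coverage) inclusion per reference gene; targets are suffixed '_T'."""
    if not (0.0 <= coverage <= 1.0):
        raise ValueError(f"coverage must be in [0, 1], got {coverage}")
    rng = np.random.default_rng(seed)
    genes = sorted(
        {g for pid in h.roots for g in h.subtree_genes(pid)},
        key=lambda g: g.symbol,
    )
    lines = []
    for g in genes:
        if rng.random() < coverage:
            lines.append(f"{g.symbol}\t{g.symbol}_T\n")
    text = "# reference\ttarget\n" + "".join(lines)
    return parse_ortholog_map(io.StringIO(text), "reference", "target"), text


def gen_expression(
    h: PathwayHierarchy, m: OrthologMap, p: GenParams
) -> str:
    """Expression TSV: DE genes get ratios of magnitude ~de_effect, others near 0.

    Only orthologous genes are emitted (the overlay denominator counts
    orthologous proteins).  A Bernoulli(frac_de) draw marks each gene DE;
    DE ratios are sign-equiprobable de_effect plus Normal(0, 0.05 x
    de_effect) noise, non-DE ratios are Uniform(-0.3, 0.3) — comfortably
    inside the default 2-fold cutoff.
    """
    rng = np.random.default_rng(p.seed + 1)
    mapped = m.reference_genes()
    genes = sorted(
        {g for pid in h.roots for g in h.subtree_genes(pid) if g in mapped},
        key=lambda g: g.symbol,
    )
    lines = ["entrez\tsymbol\tlog2_ratio\n"]
    for g in genes:
        if rng.random() < p.frac_de:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            ratio = sign * (p.de_effect + rng.normal(0.0, 0.05 * p.de_effect))
        else:
            ratio = rng.uniform(-0.3, 0.3)
        entrez = "" if g.entrez is None else str(g.entrez)
        lines.append(f"{entrez}\t{g.symbol}\t{ratio:.6f}\n")
    return "".join(lines)


def gen_rate_limiting(
    genes: list[GeneID], fraction: float, seed: int
) -> str:
    """Deterministic Bernoulli(fraction) rate-limiting flags, one gene per line."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    lines = []
    for g in sorted(genes, key=lambda g: g.symbol):
        flag = 1 if rng.random() < fraction else 0
        lines.append(f"{g.symbol}\t{flag}\n")
    return "".join(lines)
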