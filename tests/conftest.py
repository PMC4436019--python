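"""Shared fixtures: small hand-built hierarchies and random-instance builders."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings as hyp_settings

from pathburst.model_io import GeneID, PathwayHierarchy, build_hierarchy

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")


def make_hierarchy(
    edges: list[tuple[str, str]], genes: dict[str, set[str]]
) -> PathwayHierarchy:
    """Shorthand builder taking plain symbol strings."""
    gene_sets = {pid: {GeneID(s) for s in syms} for pid, syms in genes.items()}
    return build_hierarchy(edges, gene_sets)


@pytest.fixture
def chain3() -> PathwayHierarchy:
    """Three-level chain P1 > P2 > P3 with overlapping direct gene sets."""
    return make_hierarchy(
        [("P1", "P2"), ("P2", "P3")],
        {"P1": {"A"}, "P2": {"A", "B"}, "P3": {"B", "C"}},
    )


@pytest.fixture
def two_level() -> PathwayHierarchy:
    """One root, two level-2 pathways sharing one gene (crosstalk at level 2)."""
    return make_hierarchy(
        [("R", "P1"), ("R", "P2")],
        {"P1": {"A", "B", "S"}, "P2": {"C", "S"}},
    )


def random_forest(rng: random.Random, max_nodes: int = 20) -> PathwayHierarchy:
    """A random rooted forest with random gene placement, for oracle tests."""
    n = rng.randint(1, max_nodes)
    ids = [f"N{i:03d}" for i in range(n)]
    edges = []
    for i in range(1, n):
        # parent chosen among earlier nodes keeps it acyclic
        parent = ids[rng.randrange(i)]
        edges.append((parent, ids[i]))
    symbols = [f"G{i}" for i in range(rng.randint(1, 30))]
    genes: dict[str, set[str]] = {}
    for pid in ids:
        k = rng.randint(0, min(5, len(symbols)))
        genes[pid] = set(rng.sample(symbols, k))
    return make_hierarchy(edges, genes)


def flat_level2(
    rng: random.Random, max_pathways: int = 8, max_genes: int = 30
) -> PathwayHierarchy:
    """One root with up to ``max_pathways`` leaf children at level 2."""
    p = rng.randint(2, max_pathways)
    symbols = [f"G{i}" for i in range(rng.randint(1, max_genes))]
    genes = {}
    edges = []
    for i in range(p):
        pid = f"P{i:02d}"
        edges.append(("ROOT", pid))
        k = rng.randint(0, len(symbols))
        genes[pid] = set(rng.sample(symbols, k))
    return make_hierarchy(edges, genes)
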