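"""Pathway hierarchy model and input parsers.

The hierarchy is a rooted forest of pathways: a 2-column TSV gives
parent/child relations (the dialect of Reactome's public relation export,
``#`` comments allowed) and a GMT file gives per-pathway gene membership.
A pathway's full gene complement is the union of its own genes and those
of all its sub-pathways.

Depth convention: roots are depth (level) 1, their children level 2, and
so on — "level two" is the second ring of the sunburst.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx

__all__ = [
    "GeneID",
    "PathwayNode",
    "PathwayHierarchy",
    "ParseError",
    "StructureError",
    "parse_relations",
    "parse_gmt",
    "build_hierarchy",
]


class ParseError(ValueError):
    """A malformed input line; the message names the 1-based line number."""


class StructureError(ValueError):
    """The relations do not form a forest (multi-parent node or cycle)."""


@dataclass(frozen=True)
class GeneID:
    """A gene identified by symbol (required) and optional Entrez number.

    Symbols are case-insensitive; the canonical form is upper case.
    Identity (equality/hash) is the canonical symbol, which is the only
    identifier GMT membership carries.  Cross-referencing against records
    that may carry an Entrez number goes through :meth:`matches`, where
    Entrez, when present on both sides, takes precedence.
    """

    symbol: str
    entrez: int | None = None

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ValueError("GeneID requires a non-empty symbol")
        object.__setattr__(self, "symbol", self.symbol.strip().upper())
        if self.entrez is not None and self.entrez <= 0:
            raise ValueError(f"Entrez ID must be positive, got {self.entrez}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneID):
            return NotImplemented
        return self.symbol == other.symbol

    def __hash__(self) -> int:
        return hash(self.symbol)

    def matches(self, other: "GeneID") -> bool:
        """Entrez-first comparison: numbers decide when both sides have one."""
        if self.entrez is not None and other.entrez is not None:
            return self.entrez == other.entrez
        return self.symbol == other.symbol


@dataclass
class PathwayNode:
    pathway_id: str
    name: str
    parent_id: str | None = None
    direct_genes: set[GeneID] = field(default_factory=set)


class PathwayHierarchy:
    """A rooted forest of pathway nodes with per-node gene sets.

    Roots are ordered lexicographically by pathway_id, as are siblings;
    this fixed ordering is what the sunburst layout and all reports use.
    """

    def __init__(self, nodes: dict[str, PathwayNode]):
        self.nodes = nodes
        self._children: dict[str, list[str]] = {pid: [] for pid in nodes}
        roots = []
        for pid, node in nodes.items():
            if node.parent_id is None:
                roots.append(pid)
            else:
                if node.parent_id not in nodes:
                    raise StructureError(
                        f"parent {node.parent_id!r} of {pid!r} is not a known pathway"
                    )
                self._children[node.parent_id].append(pid)
        self.roots: list[str] = sorted(roots)
        for kids in self._children.values():
            kids.sort()
        self._depth: dict[str, int] = {}
        for root in self.roots:
            stack = [(root, 1)]
            while stack:
                pid, d = stack.pop()
                self._depth[pid] = d
                stack.extend((c, d + 1) for c in self._children[pid])

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.nodes

    def children(self, pathway_id: str) -> list[str]:
        return list(self._children[pathway_id])

    def depth(self, pathway_id: str) -> int:
        return self._depth[pathway_id]

    @property
    def height(self) -> int:
        return max(self._depth.values(), default=0)

    def walk(self, pathway_id: str | None = None) -> Iterator[str]:
        """Pre-order traversal (lexicographic siblings) of a subtree or all roots."""
        stack = sorted(self.roots, reverse=True) if pathway_id is None else [pathway_id]
        if pathway_id is not None and pathway_id not in self.nodes:
            raise KeyError(pathway_id)
        while stack:
            pid = stack.pop()
            yield pid
            stack.extend(reversed(self._children[pid]))

    def subtree_genes(self, pathway_id: str) -> set[GeneID]:
        """Union of direct genes over the node and all its descendants."""
        genes: set[GeneID] = set()
        for pid in self.walk(pathway_id):
            genes |= self.nodes[pid].direct_genes
        return genes

    def nodes_at_depth(self, depth: int) -> list[str]:
        """Pathways on ring ``depth`` (roots are 1), in layout order."""
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        level = list(self.roots)
        for _ in range(depth - 1):
            level = [c for pid in level for c in self._children[pid]]
        return level

    def leaf_count(self, pathway_id: str) -> int:
        """Number of leaf descendants; a leaf counts itself."""
        if pathway_id not in self.nodes:
            raise KeyError(pathway_id)
        n = 0
        for pid in self.walk(pathway_id):
            if not self._children[pid]:
                n += 1
        return n

    # -- canonical JSON serialization ------------------------------------

    def to_json(self) -> str:
        payload = {
            "nodes": [
                {
                    "pathway_id": pid,
                    "name": node.name,
                    "parent_id": node.parent_id,
                    "genes": sorted(
                        [g.symbol, g.entrez] for g in node.direct_genes
                    ),
                }
                for pid, node in sorted(self.nodes.items())
            ]
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PathwayHierarchy":
        payload = json.loads(text)
        nodes = {}
        for rec in payload["nodes"]:
            nodes[rec["pathway_id"]] = PathwayNode(
                pathway_id=rec["pathway_id"],
                name=rec["name"],
                parent_id=rec["parent_id"],
                direct_genes={GeneID(sym, ez) for sym, ez in rec["genes"]},
            )
        return cls(nodes)


def _lines(stream: IO[str] | Iterable[str] | str) -> Iterator[tuple[int, str]]:
    if isinstance(stream, str):
        stream = stream.splitlines()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def parse_relations(stream: IO[str] | Iterable[str] | str) -> list[tuple[str, str]]:
    """Read parent/child pathway relations from 2-column TSV.

    Duplicate identical edges are collapsed (first occurrence kept); a child
    listed under two distinct parents violates the forest structure and
    raises :class:`StructureError`.
    """
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    parent_of: dict[str, str] = {}
    for lineno, line in _lines(stream):
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        parent, child = fields[0].strip(), fields[1].strip()
        if (parent, child) in seen:
            continue
        if child in parent_of and parent_of[child] != parent:
            raise StructureError(
                f"line {lineno}: pathway {child!r} has two parents "
                f"({parent_of[child]!r} and {parent!r}); the hierarchy must be a forest"
            )
        parent_of[child] = parent
        seen.add((parent, child))
        edges.append((parent, child))
    return edges


def parse_gmt(stream: IO[str] | Iterable[str] | str) -> dict[str, set[GeneID]]:
    """Read GMT gene membership: set id, description, then gene symbols.

    Symbols are canonicalized upper-case; duplicates within a line collapse.
    """
    gene_sets: dict[str, set[GeneID]] = {}
    for lineno, line in _lines(stream):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(
                f"line {lineno}: GMT line needs at least 2 fields (id, description)"
            )
        pathway_id = fields[0].strip()
        genes = {GeneID(sym) for sym in fields[2:] if sym.strip()}
        gene_sets[pathway_id] = genes
    return gene_sets


def build_hierarchy(
    edges: list[tuple[str, str]],
    gene_sets: dict[str, set[GeneID]] | None = None,
    names: dict[str, str] | None = None,
) -> PathwayHierarchy:
    """Assemble the forest from relation edges and GMT gene sets.

    Every pathway named in either input becomes a node; pathways appearing
    only in gene_sets become roots.  A cycle in the edges raises
    :class:`StructureError` listing one offending cycle.
    """
    gene_sets = gene_sets or {}
    names = names or {}

    g = nx.DiGraph()
    g.add_edges_from(edges)
    try:
        cycle = nx.find_cycle(g, orientation="original")
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[0][0]}"
        raise StructureError(f"cycle in pathway relations: {path}")

    parent_of: dict[str, str] = {}
    for parent, child in edges:
        if child in parent_of and parent_of[child] != parent:
            raise StructureError(f"pathway {child!r} has two parents")
        parent_of[child] = parent

    all_ids = set(parent_of) | {p for p, _ in edges} | set(gene_sets)
    nodes = {
        pid: PathwayNode(
            pathway_id=pid,
            name=names.get(pid, pid),
            parent_id=parent_of.get(pid),
            direct_genes=set(gene_sets.get(pid, set())),
        )
        for pid in all_ids
    }
    return PathwayHierarchy(nodes)


def load_hierarchy(
    relations_path: str, gmt_path: str | None = None
) -> PathwayHierarchy:
    """Convenience loader from file paths (UTF-8, LF or CRLF)."""
    with open(relations_path, encoding="utf-8") as fh:
        edges = parse_relations(fh)
    gene_sets: dict[str, set[GeneID]] = {}
    if gmt_path is not None:
        with open(gmt_path, encoding="utf-8") as fh:
            gene_sets = parse_gmt(fh)
    return build_hierarchy(edges, gene_sets)
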