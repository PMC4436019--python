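# Methods

## The model

The object of study is a rooted forest of pathways. Each node carries a
set of *direct* genes; the gene complement of a pathway is the union of
direct genes over the node and all of its descendants, so a parent's
complement always contains each child's. Roots sit at level 1. Two input
dialects define the forest: a 2-column TSV of (parent, child) pathway ids
(comments with `#`, duplicate edges collapsed) and GMT gene membership
(set id, description, symbols). A pathway listed under two distinct
parents is rejected rather than duplicated: the radial layout requires a
tree, and a duplication policy would silently double-count genes in every
downstream statistic. Gene symbols are case-insensitive and canonicalized
upper-case; an Entrez number, when both sides of a comparison carry one,
takes precedence over the symbol (expression records frequently use
symbol aliases, while Entrez IDs are stable).

Internal nodes may carry direct genes of their own. Reference hierarchies
differ on whether a parent's membership is exactly the union of its
children; allowing direct genes on internal nodes covers both conventions
with the union-based complement as the single definition.

## Ortholog projection

An ortholog map is a many-to-many set of (reference gene, target gene)
pairs. Presence is evaluated on the reference side only: a reference gene
either has at least one target ortholog or it does not, and the
multiplicity of target orthologs is irrelevant to pathway status. With
M the set of mapped reference genes and G a pathway's gene complement:

- **complete** — G ⊆ M and G ≠ ∅
- **empty** — G ∩ M = ∅ (including G = ∅, flagged `gene_less` in the
  projection so degenerate pathways are distinguishable from true absence)
- **partial** — otherwise

These three statuses are exhaustive and mutually exclusive, and status is
monotone under map growth (empty → partial → complete). A complete parent
implies every descendant is complete or gene-less, because descendants'
complements are subsets of the parent's.

The per-gene ortholog table reports, for each orthologous gene of a
pathway, a "number of gene products" column computed as the number of
leaf sub-pathways under the selected pathway that contain the gene. The
notion of a per-gene product count inside a pathway is not standardized;
this leaf-occurrence count is our operational definition and is isolated
in one function (`ortholog.n_products`) so it can be swapped. The
rate-limiting column is an input annotation (TSV of symbol, 0/1), not
computed: no rule exists to derive flux control from membership data
alone.

## Crosstalk

Crosstalk is evaluated among the pathways of one hierarchy level (default
level 2; levels of a tree have disjoint subtrees, so shared membership
between two same-level pathways is genuine interconnection rather than
nesting). The index maps each gene to the level-nodes whose complement
contains it; genes with ≥ 2 memberships are cross-talking, and each
unordered pathway pair sharing ≥ 1 gene yields one edge with the shared
set. A gene in k pathways contributes to exactly C(k, 2) edges — this
identity, plus equivalence with an exhaustive all-pairs intersection, is
asserted in tests. A gene in a single pathway has a crosstalk count of 0,
not 1: the count answers "how many pathways does this gene interconnect",
which requires at least two memberships. Cross-level edges are undefined
and excluded.

## Expression overlay

Input ratios are log2 fold changes between two biological states
(`--linear-ratio` applies log2 on load for linear inputs). Classification
at cutoff c > 0: UP when ratio ≥ c, DOWN when ratio ≤ −c, boundary
inclusive; the default c = 1.0 (2-fold) is the conventional fold-change
screen. Records are matched only against a pathway's *orthologous* genes,
Entrez first then symbol; this keeps the per-pathway DE ratio

    de_ratio = (n_up + n_down) / n_ortho

bounded by 1 (defined 0 when n_ortho = 0). Duplicate records for one gene
keep the largest |log2 ratio| (the conservative choice for a screen —
it never hides a signal) with a logged warning; rows with missing or
non-finite ratios are dropped and counted.

## OOMM encoding

A non-negative magnitude v is shown as A × 10^B: digit A on a narrow
bar, integer exponent B on a wide bar, both linear 0–10 scales
(99 → 9.9 × 10¹, wide 1 / narrow 9.9). Edge policies, chosen here because
the 0–10 scales leave them open: v ∈ (0, 1) keeps B = 0 and A = v, so the
encoding stays invertible without a negative exponent; v = 0 → (0, 0);
v ≥ 10¹¹ saturates at (10, 10) with an explicit flag, and decoding a
saturated encoding raises rather than returning a wrong magnitude.
Power-of-ten boundaries are corrected after the floating-point log10 so
encode(10^k) = (1.0, k) exactly for k = 0…10.

## Sunburst layout and SVG

Depth d occupies the annulus [inner + (d−1)·w, inner + d·w) with
inner radius 60 px and ring width 36 px by default (pure display
constants, configurable). Roots partition the full circle proportionally
to their leaf counts; each node's children partition the parent's
interval the same way, in lexicographic pathway-id order. Equal weight
per leaf is the convention of the D3 partition family this layout
follows; it keeps deep branches readable and, with the fixed sibling
order, makes the layout — and the emitted SVG — byte-deterministic.
Angles start at 12 o'clock and grow clockwise. Sibling intervals are
half-open, so conservation (child spans sum to the parent's, root spans
to 2π) holds to 1e-9 and siblings never overlap.

Arc fill encodes ortholog status (complete #4daf4a green, partial
#ffd92f yellow, empty #984ea3 purple) or DE ratio through the
sequential white→red `Reds` ramp (0 → light, 1 → dark). Up/down OOMM
bar channels use yellow/blue. OOMM dual bars are two radial rectangles
at the arc's angular midpoint on its outer edge; crosstalk edges are
quadratic chords through the center between arc midpoints at inner
radii, stroke width growing with log10 of the shared-gene count. Edges
whose endpoint was pruned by `--max-depth` are skipped with a warning.
Interactive exploration (click-to-expand) is replaced by re-invocation:
`render --root <pathway>` lays out the subtree as its own full-circle
sunburst with the subtree root on ring 1.

## Synthetic data

The generator emulates a study comparing a reference species with a
target: a complete b-ary pathway forest (defaults: 3 roots, 3 levels,
branching 3 → 39 pathways, 27 leaves), 8 unique genes per leaf, with a
fraction (default 0.1) of all genes inserted into a second random leaf to
induce crosstalk. Ortholog coverage (default 0.8) and DE status (default
frac_de 0.3) are independent Bernoulli draws per gene, so both rates are
recoverable within binomial error by construction. DE genes get log2
ratios of ±de_effect (default 3, sign equiprobable) plus
Normal(0, 0.05·de_effect) noise; non-DE genes get Uniform(−0.3, 0.3),
well inside the default cutoff. One `numpy` Generator seeded per call
makes every stream bit-stable. Fabricated Entrez IDs live above
900,000,000 to avoid collision with real identifiers.

What the generator does **not** emulate: real Reactome topology (highly
unbalanced, with direct genes on internal nodes), correlated ortholog
loss along gene families, pathway-coherent (rather than independent)
differential expression, and measurement noise structure. Passing tests
therefore demonstrate correctness of the algorithms and input handling,
not biological realism of any particular projection.

## Problem sizes and numerical choices

Oracle-equivalence tests run 200 random instances of ≤ 8 pathways and
≤ 30 genes against exhaustive nested-loop references, and 200 random
forests (≤ 20 nodes) for layout conservation; the recovery tests use
1,350-gene (coverage) and 1,000-gene (DE fraction) worlds with 3-binomial-SD
bands — sizes at which the binomial bound is tight enough to catch an
implementation error yet the whole suite runs in seconds. Angular
tolerances are 1e-9 absolute; OOMM round trip is 1e-9 relative. Ties in
all orderings break lexicographically by pathway id; tables sort stably
so re-sorting by an all-equal column preserves order.

## Known limitations

- Strict tree: DAG-shaped hierarchies (shared sub-pathways) are rejected.
- The "number of gene products" column is an operational stand-in (see
  above), not a curated product count.
- The DE denominator counts distinct orthologous *genes*; if a dataset
  distinguishes protein isoforms, they collapse to one gene.
- SVG output has no labels or interactivity; it is an overview figure,
  with re-rooting as the drill-down mechanism.
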