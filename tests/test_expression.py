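"""Expression parsing, DE classification and per-pathway summaries."""

import random

import pytest

from pathburst.crosstalk import build_index
from pathburst.expression import (
    DEStatus,
    ExpressionConfig,
    ExpressionRecord,
    classify_de,
    gene_table,
    parse_expression,
    summarize_all,
    summarize_pathway,
)
from pathburst.model_io import GeneID, ParseError
from pathburst.ortholog import project
from tests.conftest import make_hierarchy, random_forest
from tests.test_ortholog import map_of

CFG = ExpressionConfig(cutoff=1.0)


def rec(symbol: str, ratio: float, entrez: int | None = None) -> ExpressionRecord:
    return ExpressionRecord(GeneID(symbol, entrez), ratio)


class TestParseExpression:
    def test_single_record(self):
        out = parse_expression("entrez\tsymbol\tlog2_ratio\n7157\tTP53\t2.0\n")
        assert out == [rec("TP53", 2.0, 7157)]

    def test_nan_row_dropped_with_warning(self, caplog):
        text = "entrez\tsymbol\tlog2_ratio\n\tA\tNaN\n\tB\t1.0\n"
        with caplog.at_level("WARNING"):
            out = parse_expression(text)
        assert [r.gene.symbol for r in out] == ["B"]
        assert "dropped 1" in caplog.text

    def test_missing_column_is_parse_error(self):
        with pytest.raises(ParseError, match="log2_ratio"):
            parse_expression("entrez\tsymbol\n1\tA\n")

    def test_empty_stream_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_expression("")

    def test_duplicate_keeps_largest_magnitude(self):
        text = "entrez\tsymbol\tlog2_ratio\n\tA\t0.5\n\tA\t-3.0\n\tA\t1.0\n"
        out = parse_expression(text)
        assert out == [rec("A", -3.0)]

    def test_linear_ratio_log2_applied(self):
        out = parse_expression("entrez\tsymbol\tlog2_ratio\n\tA\t4.0\n",
                               linear_ratio=True)
        assert out[0].log2_ratio == pytest.approx(2.0)


class TestClassifyDE:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (2.0, DEStatus.UP),
            (-2.0, DEStatus.DOWN),
            (0.5, DEStatus.UNCHANGED),
            (1.0, DEStatus.UP),      # boundary inclusive
            (-1.0, DEStatus.DOWN),
        ],
    )
    def test_threshold_rule(self, ratio, expected):
        assert classify_de(rec("A", ratio), CFG) is expected

    def test_cutoff_must_be_positive(self):
        with pytest.raises(ValueError):
            ExpressionConfig(cutoff=0.0)


@pytest.fixture
def world():
    """4-gene pathway, fully orthologous, for summary arithmetic."""
    h = make_hierarchy([("R", "P")], {"P": {"A", "B", "C", "D"}})
    m = map_of("A", "B", "C", "D")
    return h, m, project(h, m)


class TestSummarize:
    def test_no_matched_records(self, world):
        h, m, proj = world
        s = summarize_pathway(h, "P", [], proj, CFG, m)
        assert (s.n_up, s.n_down, s.de_ratio) == (0, 0, 0.0)

    def test_one_up_one_down_of_four(self, world):
        h, m, proj = world
        records = [rec("A", 2.0), rec("B", -2.0), rec("C", 0.1)]
        s = summarize_pathway(h, "P", records, proj, CFG, m)
        assert (s.n_up, s.n_down, s.n_ortho) == (1, 1, 4)
        assert s.de_ratio == pytest.approx(0.5)

    def test_unknown_pathway(self, world):
        h, m, proj = world
        with pytest.raises(KeyError):
            summarize_pathway(h, "NOPE", [], proj, CFG, m)

    def test_non_orthologous_genes_excluded(self):
        # only A has an ortholog; a DE record for B must not count
        h = make_hierarchy([("R", "P")], {"P": {"A", "B"}})
        m = map_of("A")
        proj = project(h, m)
        s = summarize_pathway(h, "P", [rec("B", 5.0)], proj, CFG, m)
        assert (s.n_up + s.n_down, s.n_ortho) == (0, 1)

    def test_entrez_match_beats_symbol_mismatch(self):
        h = make_hierarchy([], {"P": set()})
        h.nodes["P"].direct_genes.add(GeneID("TP53", 7157))
        m = map_of("TP53")
        proj = project(h, m)
        # record under an alias symbol but the right Entrez number
        s = summarize_pathway(h, "P", [rec("P53ALIAS", 3.0, 7157)], proj, CFG, m)
        assert s.n_up == 1

    def test_symbol_match_case_insensitive(self, world):
        h, m, proj = world
        s1 = summarize_pathway(h, "P", [rec("a", 3.0)], proj, CFG, m)
        s2 = summarize_pathway(h, "P", [rec("A", 3.0)], proj, CFG, m)
        assert (s1.n_up, s2.n_up) == (1, 1)

    def test_matches_bruteforce_oracle(self):
        rng = random.Random(37)
        for _ in range(15):
            h = random_forest(rng)
            symbols = sorted(
                {g.symbol for pid in h.roots for g in h.subtree_genes(pid)}
            )
            covered = [s for s in symbols if rng.random() < 0.7]
            m = map_of(*covered)
            proj = project(h, m)
            records = [
                rec(s, rng.uniform(-4, 4)) for s in symbols if rng.random() < 0.8
            ]
            summaries = summarize_all(h, records, proj, CFG, m)
            by_symbol = {r.gene.symbol: r.log2_ratio for r in records}
            for pid in h.nodes:
                # oracle: nested-loop match and count
                up = down = 0
                for g in h.subtree_genes(pid):
                    if g.symbol not in set(covered) or g.symbol not in by_symbol:
                        continue
                    v = by_symbol[g.symbol]
                    if v >= 1.0:
                        up += 1
                    elif v <= -1.0:
                        down += 1
                assert (summaries[pid].n_up, summaries[pid].n_down) == (up, down)
                assert 0.0 <= summaries[pid].de_ratio <= 1.0


class TestInvariants:
    def test_cutoff_monotonicity(self):
        rng = random.Random(41)
        h = random_forest(rng)
        symbols = sorted({g.symbol for pid in h.roots for g in h.subtree_genes(pid)})
        m = map_of(*symbols)
        proj = project(h, m)
        records = [rec(s, rng.uniform(-4, 4)) for s in symbols]
        prev = None
        for cutoff in (0.5, 1.0, 2.0):
            summaries = summarize_all(
                h, records, proj, ExpressionConfig(cutoff), m)
            if prev is not None:
                for pid in h.nodes:
                    assert summaries[pid].n_up <= prev[pid].n_up
                    assert summaries[pid].n_down <= prev[pid].n_down
            prev = summaries

    def test_parent_dominates_children(self):
        rng = random.Random(43)
        for _ in range(10):
            h = random_forest(rng)
            symbols = sorted({g.symbol for pid in h.roots for g in h.subtree_genes(pid)})
            m = map_of(*symbols)
            proj = project(h, m)
            records = [rec(s, rng.uniform(-4, 4)) for s in symbols]
            summaries = summarize_all(h, records, proj, CFG, m)
            for pid in h.nodes:
                de = summaries[pid].n_up + summaries[pid].n_down
                for c in h.children(pid):
                    assert de >= summaries[c].n_up + summaries[c].n_down


class TestGeneTable:
    def test_empty_when_nothing_matches(self, world):
        h, m, proj = world
        assert gene_table(h, "P", [], proj, None, None, CFG, m) == []

    def test_rows_agree_with_components(self, two_level):
        m = map_of("A", "B", "C", "S")
        proj = project(two_level, m)
        idx = build_index(two_level, 2)
        records = [rec("A", 2.0), rec("S", -1.5), rec("C", 0.2)]
        rows = gene_table(two_level, "R", records, proj, idx, {GeneID("A"): True},
                          CFG, m)
        by = {r.symbol: r for r in rows}
        assert set(by) == {"A", "S", "C"}
        assert by["A"].status is DEStatus.UP and by["A"].rate_limiting
        assert by["S"].status is DEStatus.DOWN
        assert by["S"].n_crosstalk_pathways == 2
        assert by["C"].status is DEStatus.UNCHANGED

    def test_row_count_is_matched_orthologous(self):
        rng = random.Random(47)
        for _ in range(10):
            h = random_forest(rng)
            symbols = sorted({g.symbol for pid in h.roots for g in h.subtree_genes(pid)})
            covered = {s for s in symbols if rng.random() < 0.6}
            m = map_of(*covered)
            proj = project(h, m)
            records = [rec(s, 2.0) for s in symbols if rng.random() < 0.5]
            rec_syms = {r.gene.symbol for r in records}
            for pid in list(h.nodes)[:5]:
                rows = gene_table(h, pid, records, proj, None, None, CFG, m)
                expected = {
                    g.symbol
                    for g in h.subtree_genes(pid)
                    if g.symbol in covered and g.symbol in rec_syms
                }
                assert {r.symbol for r in rows} == expected
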