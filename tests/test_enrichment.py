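"""Hypergeometric over-representation, BH adjustment, and the C-T-P network."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from herbnet.enrichment import (
    GeneSet,
    GeneSetCollection,
    bh_adjust,
    build_ctp_network,
    fisher_enrichment,
    read_gmt,
    round_half_up,
    write_gmt,
)
from herbnet.io_model import TargetSet

from _oracles import hypergeom_tail_closed_form


def _collection(**sets):
    return GeneSetCollection(
        GeneSet(term_id=k, name=k.lower(), members=frozenset(v)) for k, v in sets.items()
    )


class TestFisherEnrichment:
    def test_full_overlap_closed_form(self):
        bg = TargetSet("bg", [f"G{i}" for i in range(10)])
        term = [f"G{i}" for i in range(5)]
        res = fisher_enrichment(TargetSet("q", term), _collection(T1=term), bg)
        assert res.loc[0, "p_value"] == pytest.approx(1 / 252, rel=1e-12)

    def test_disjoint_query_p_is_one(self):
        bg = TargetSet("bg", [f"G{i}" for i in range(10)])
        res = fisher_enrichment(
            TargetSet("q", ["G6", "G7"]), _collection(T1=["G0", "G1"]), bg
        )
        assert res.loc[0, "k"] == 0 and res.loc[0, "p_value"] == 1.0

    def test_single_term_fdr_equals_p(self):
        bg = TargetSet("bg", [f"G{i}" for i in range(8)])
        res = fisher_enrichment(
            TargetSet("q", ["G0", "G1"]), _collection(T1=["G0", "G3"]), bg
        )
        assert res.loc[0, "fdr"] == res.loc[0, "p_value"]

    def test_query_clipped_to_background(self):
        bg = TargetSet("bg", ["G0", "G1", "G2"])
        res = fisher_enrichment(
            TargetSet("q", ["G0", "ALIEN"]), _collection(T1=["G0", "G1"]), bg
        )
        assert res.attrs["clipped"] == ["ALIEN"]
        assert res.loc[0, "n"] == 1

    def test_term_outside_background_skipped(self):
        bg = TargetSet("bg", ["G0", "G1"])
        res = fisher_enrichment(
            TargetSet("q", ["G0"]), _collection(T1=["G0"], T2=["ELSEWHERE"]), bg
        )
        assert res.attrs["skipped_terms"] == ["T2"]
        assert list(res["term"]) == ["T1"]

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            fisher_enrichment(TargetSet("q", []), _collection(T1=["G0"]), TargetSet("bg", []))

    def test_k_equals_independent_recount(self):
        bg = TargetSet("bg", [f"G{i}" for i in range(20)])
        q = TargetSet("q", [f"G{i}" for i in range(0, 10, 2)])
        terms = {f"T{j}": [f"G{i}" for i in range(j, j + 6)] for j in range(4)}
        res = fisher_enrichment(q, _collection(**terms), bg).set_index("term")
        for t, members in terms.items():
            assert res.loc[t, "k"] == len(set(members) & q.symbols)

    @settings(max_examples=40, deadline=None)
    @given(
        N=st.integers(2, 12),
        data=st.data(),
    )
    def test_matches_closed_form_oracle(self, N, data):
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        bg = [f"G{i}" for i in range(N)]
        term = bg[:K]
        query = bg[-n:]
        res = fisher_enrichment(
            TargetSet("q", query), _collection(T1=term), TargetSet("bg", bg)
        )
        k = int(res.loc[0, "k"])
        expected = hypergeom_tail_closed_form(N, K, n, k)
        assert res.loc[0, "p_value"] == pytest.approx(expected, rel=1e-10)


class TestBHAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.2]) == [0.2]

    def test_sorted_input_gives_nondecreasing_fdr(self):
        ps = [0.001, 0.01, 0.02, 0.5, 0.9]
        fdr = bh_adjust(ps)
        assert fdr == sorted(fdr)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0, allow_nan=False), min_size=1, max_size=30))
    def test_matches_statsmodels(self, ps):
        ours = bh_adjust(ps)
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert ours == pytest.approx(list(theirs), rel=1e-9)


class TestCTPNetwork:
    def test_pathway_coverage_percentage(self):
        core = TargetSet("core", [f"G{i}" for i in range(40)])
        pw = _collection(P1=[f"G{i}" for i in range(21)])
        ctp = build_ctp_network({}, core, pw)
        row = ctp.pathway_table.iloc[0]
        assert row["n_core_targets"] == 21 and row["pct_core_targets"] == 52.5

    def test_disjoint_pathway_retained_with_zero(self):
        core = TargetSet("core", ["G0", "G1"])
        ctp = build_ctp_network({}, core, _collection(P1=["OTHER"]))
        row = ctp.pathway_table.iloc[0]
        assert row["n_core_targets"] == 0 and row["pct_core_targets"] == 0.0

    def test_toy_tripartite_counts(self):
        # 3 compounds x 2 targets each, 4 core targets, pathways covering 3 and 1
        core = TargetSet("core", ["T1", "T2", "T3", "T4"])
        links = {"c1": ["T1", "T2"], "c2": ["T2", "T3"], "c3": ["T3", "T4"]}
        pw = _collection(P1=["T1", "T2", "T3"], P2=["T4"])
        ctp = build_ctp_network(links, core, pw)
        assert ctp.n_nodes == 9  # 3 compounds + 4 targets + 2 pathways
        assert ctp.n_edges == 10  # 6 compound-target + 4 target-pathway

    def test_compound_without_core_link_excluded(self):
        core = TargetSet("core", ["T1"])
        links = {"c1": ["T1"], "c2": ["ELSEWHERE"]}
        ctp = build_ctp_network(links, core, _collection(P1=["T1"]))
        assert ctp.n_compounds == 1

    def test_ranking_by_count_then_name(self):
        core = TargetSet("core", ["T1", "T2", "T3"])
        pw = _collection(B=["T1"], A=["T2"], C=["T1", "T2"])
        ctp = build_ctp_network({}, core, pw)
        assert list(ctp.pathway_table["pathway"]) == ["c", "a", "b"]


class TestGMT:
    def test_roundtrip(self, tmp_path):
        coll = _collection(T1=["G1", "G2"], T2=["G3"])
        p = tmp_path / "sets.gmt"
        write_gmt(coll, p)
        back = read_gmt(p)
        assert {gs.term_id: gs.members for gs in back} == {gs.term_id: gs.members for gs in coll}

    def test_empty_set_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("T1\tdesc\t\n")
        with pytest.raises(Exception):
            read_gmt(p)


@pytest.mark.parametrize(
    "value,expected",
    [(52.45, 52.5), (52.44, 52.4), (0.05, 0.1), (17.5, 17.5), (-0.25, -0.3)],
)
def test_round_half_up(value, expected):
    assert round_half_up(value, 1) == expected
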