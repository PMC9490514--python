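"""Bipartite and PPI construction, dialect handling, centrality conventions."""

import networkx as nx
import pytest

from herbnet.io_model import FormatError
from herbnet.network_build import (
    PPINetwork,
    UnknownNodeError,
    build_ct_network,
    build_ppi_network,
    compute_centralities,
    read_string_edges,
)

from _oracles import brute_force_centralities


class TestBipartite:
    def test_shared_targets_count_once(self):
        net = build_ct_network(["c1", "c2"], ["X", "Y"], [("c1", "X"), ("c1", "Y"), ("c2", "X"), ("c2", "Y")])
        assert net.degree("X") == 2 and net.degree("c1") == 2

    def test_duplicate_link_collapses(self):
        net = build_ct_network(["c1"], ["X"], [("c1", "X"), ("c1", "X")])
        assert net.graph.number_of_edges() == 1 and net.degree("X") == 1

    def test_unknown_node_listed(self):
        with pytest.raises(UnknownNodeError, match="c9"):
            build_ct_network(["c1"], ["X"], [("c9", "X")])

    def test_degree_flag_threshold_floor_is_seven(self):
        # 1 compound, 3 targets of degree 1: median 1, 2x median 2, floor 7 wins
        net = build_ct_network(["c1"], ["X", "Y", "Z"], [("c1", "X"), ("c1", "Y"), ("c1", "Z")])
        assert net.target_flag_threshold == 7 and net.flagged_targets == ()

    def test_planted_high_degree_targets_flagged(self):
        compounds = [f"c{i}" for i in range(10)]
        hot = ["H1", "H2"]
        cold = [f"T{i}" for i in range(8)]
        links = [(c, h) for c in compounds for h in hot]  # degree 10 >= 7
        links += [("c0", t) for t in cold]  # degree 1
        net = build_ct_network(compounds, hot + cold, links)
        assert set(net.flagged_targets) == set(hot)


class TestPPIConstruction:
    def test_threshold_boundary_inclusive(self):
        net = build_ppi_network([("A", "B", 0.69), ("B", "C", 0.70)])
        assert not net.graph.has_edge("A", "B") and net.graph.has_edge("B", "C")

    def test_self_loop_dropped(self):
        net = build_ppi_network([("A", "A", 0.9), ("A", "B", 0.9)])
        assert net.n_edges == 1 and not net.graph.has_edge("A", "A")

    def test_duplicate_pair_keeps_max_score(self):
        net = build_ppi_network([("A", "B", 0.75), ("B", "A", 0.95)])
        assert net.graph["A"]["B"]["score"] == 0.95

    def test_candidates_kept_as_isolated_nodes(self):
        net = build_ppi_network([("A", "B", 0.9)], candidates=["A", "B", "LONER"])
        assert "LONER" in net.graph and net.graph.degree("LONER") == 0

    def test_threshold_monotonicity(self):
        edges = [("A", "B", 0.72), ("B", "C", 0.8), ("C", "D", 0.95)]
        for lo, hi in [(0.7, 0.75), (0.75, 0.9), (0.9, 0.99)]:
            e_lo = set(build_ppi_network(edges, min_score=lo).graph.edges)
            e_hi = set(build_ppi_network(edges, min_score=hi).graph.edges)
            assert e_hi <= e_lo


class TestStringDialect:
    def test_milli_scores_normalized(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("protein1\tprotein2\tcombined_score\nA\tB\t700\nB\tC\t950\n")
        rows = read_string_edges(p)
        assert rows == [("A", "B", 0.7), ("B", "C", 0.95)]

    def test_unit_scores_passed_through(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("A\tB\t0.700\n")
        assert read_string_edges(p) == [("A", "B", 0.7)]

    def test_equivalent_dialects_build_same_network(self, tmp_path):
        (tmp_path / "a.tsv").write_text("A\tB\t700\nB\tC\t1000\n")
        (tmp_path / "b.tsv").write_text("A\tB\t0.7\nB\tC\t1.0\n")
        g1 = build_ppi_network(read_string_edges(tmp_path / "a.tsv")).graph
        g2 = build_ppi_network(read_string_edges(tmp_path / "b.tsv")).graph
        assert set(g1.edges) == set(g2.edges)

    def test_out_of_range_score_reports_line(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("A\tB\t0.9\nB\tC\t1500\n")
        with pytest.raises(FormatError, match="line 2"):
            read_string_edges(p)


class TestCentralities:
    def test_path_graph_conventions(self):
        net = build_ppi_network([("A", "B", 1.0), ("B", "C", 1.0)], min_score=0.5)
        t = compute_centralities(net)
        assert t.loc["B", "betweenness"] == 1.0
        assert t.loc["A", "betweenness"] == 0.0
        assert t.loc["B", "closeness"] == 1.0
        assert t.loc["A", "closeness"] == pytest.approx(2 / 3)

    def test_isolated_node_zeroes(self):
        net = build_ppi_network([("A", "B", 0.9)], candidates=["A", "B", "Z"])
        t = compute_centralities(net)
        assert t.loc["Z", "degree"] == 0
        assert t.loc["Z", "closeness"] == 0.0
        assert t.loc["Z", "betweenness"] == 0.0

    def test_empty_graph_empty_table(self):
        assert compute_centralities(PPINetwork(nx.Graph(), 0.7)).empty

    def test_complete_graph_betweenness_zero(self):
        g = nx.complete_graph(6)
        t = compute_centralities(g)
        assert (t["betweenness"] == 0).all()
        assert (t["degree"] == 5).all()

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_star_center_betweenness(self, k):
        g = nx.star_graph(k)  # node 0 is the center
        t = compute_centralities(g)
        assert t.loc[0, "betweenness"] == k * (k - 1) / 2

    def test_sum_degrees_twice_edges(self):
        g = nx.gnp_random_graph(25, 0.2, seed=7)
        t = compute_centralities(g)
        assert t["degree"].sum() == 2 * g.number_of_edges()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(12, 0.25, seed=seed)
        deg, clo, btw = brute_force_centralities(g.nodes, g.edges)
        t = compute_centralities(g)
        for v in g.nodes:
            assert t.loc[v, "degree"] == deg[v]
            assert t.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-12)
            assert t.loc[v, "betweenness"] == pytest.approx(btw[v], abs=1e-9)
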