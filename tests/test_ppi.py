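from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from _oracles import brute_betweenness
from netpharm.models import PPIEdge
from netpharm.ppi import (
    build_ppi_graph,
    centrality_metrics,
    edge_count_from_degrees,
    induced_subgraph,
    remove_isolates,
    screen_key_targets,
)


class TestBuildGraph:
    def test_threshold_inclusive(self):
        edges = [PPIEdge("A", "B", 0.39), PPIEdge("B", "C", 0.40), PPIEdge("C", "D", 0.95)]
        g = build_ppi_graph(edges, ["A", "B", "C", "D"], 0.4)
        assert g.number_of_edges() == 2
        assert not g.has_edge("A", "B")

    def test_empty_edge_list_leaves_all_isolated(self):
        g = build_ppi_graph([], ["A", "B", "C"])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 0

    def test_edge_outside_universe_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            g = build_ppi_graph([PPIEdge("A", "Z", 0.9)], ["A", "B"])
        assert g.number_of_edges() == 0
        assert "outside the universe" in caplog.text

    def test_remove_isolates_reports_removed(self):
        g = build_ppi_graph([PPIEdge("A", "B", 0.9)], ["A", "B", "C"])
        pruned, removed = remove_isolates(g)
        assert removed == ["C"]
        assert sorted(pruned.nodes) == ["A", "B"]

    def test_fully_connected_graph_unchanged(self):
        g = nx.complete_graph(4)
        pruned, removed = remove_isolates(g)
        assert removed == [] and pruned.number_of_edges() == 6


class TestCentrality:
    def test_path_center_has_unit_betweenness(self):
        g = nx.path_graph(["A", "B", "C"])
        t = centrality_metrics(g)
        assert t.set_index("gene").loc["B", "betweenness"] == pytest.approx(1.0)

    def test_star_center_has_unit_betweenness(self):
        g = nx.star_graph(4)  # center 0, four leaves
        t = centrality_metrics(g).set_index("gene")
        assert t.loc[0, "betweenness"] == pytest.approx(1.0)
        assert (t.loc[[1, 2, 3, 4], "betweenness"] == 0).all()

    def test_matches_brute_force_enumeration_on_small_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(3, 8))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)), seed=int(rng.integers(1 << 30)))
            expected = brute_betweenness(g)
            got = centrality_metrics(g).set_index("gene")["betweenness"]
            for v in g.nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-12)

    def test_values_bounded_and_leaves_zero(self):
        g = nx.balanced_tree(2, 3)
        t = centrality_metrics(g).set_index("gene")
        assert ((t["betweenness"] >= 0) & (t["betweenness"] <= 1)).all()
        for v in g.nodes:
            if g.degree(v) == 1:
                assert t.loc[v, "betweenness"] == 0.0

    def test_tiny_graph_warns_and_zeroes_betweenness(self):
        g = nx.path_graph(2)
        with pytest.warns(UserWarning):
            t = centrality_metrics(g)
        assert (t["betweenness"] == 0).all()


class TestScreening:
    def test_regular_graph_selects_nothing(self):
        t = centrality_metrics(nx.cycle_graph(4))
        assert screen_key_targets(t) == []

    def test_star_selects_center_only(self):
        t = centrality_metrics(nx.star_graph(5))
        assert screen_key_targets(t) == [0]

    def test_equals_brute_force_filter_and_row_order_invariant(self):
        g = nx.gnp_random_graph(30, 0.15, seed=7)
        t = centrality_metrics(g)
        expected = sorted(
            (row["gene"] for _, row in t.iterrows()
             if row["degree"] > t["degree"].mean()
             and row["betweenness"] > t["betweenness"].mean()),
        )
        assert sorted(screen_key_targets(t)) == expected
        shuffled = t.sample(frac=1.0, random_state=3)
        assert screen_key_targets(shuffled) == screen_key_targets(t)

    def test_output_subset_of_input(self):
        g = nx.gnp_random_graph(25, 0.2, seed=1)
        t = centrality_metrics(g)
        assert set(screen_key_targets(t)) <= set(t["gene"])


class TestSubgraphAndHandshake:
    def test_keep_all_is_identity(self):
        g = nx.gnp_random_graph(10, 0.4, seed=2)
        sub = induced_subgraph(g, list(g.nodes))
        assert nx.utils.graphs_equal(g, sub)

    def test_single_node_subgraph_has_no_edges(self):
        g = nx.complete_graph(5)
        assert induced_subgraph(g, [0]).number_of_edges() == 0

    def test_handshake_lemma_on_constructed_graphs(self):
        for seed in range(5):
            g = nx.gnp_random_graph(20, 0.3, seed=seed)
            degrees = [d for _, d in g.degree()]
            assert edge_count_from_degrees(degrees) == g.number_of_edges()

    def test_odd_degree_sum_rejected(self):
        with pytest.raises(ValueError, match="odd degree sum"):
            edge_count_from_degrees([1, 2])
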