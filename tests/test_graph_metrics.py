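"""Structural metrics, centralities and ranking comparison."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from lagnet.graph_metrics import (
    centralities,
    density,
    mean_clustering,
    node_clustering,
    path_stats,
    ranking_overlap,
    summarize,
    top_central,
)
from lagnet.lag_builder import Lag

from conftest import make_lag
from oracles import (
    adjacency,
    clustering_oracle,
    floyd_warshall,
)


def random_digraph(n, p, rng) -> Lag:
    a = (rng.random((n, n)) < p) & ~np.eye(n, dtype=bool)
    g = nx.from_numpy_array(a.astype(int), create_using=nx.DiGraph)
    nx.set_edge_attributes(g, 1, "weight")
    return Lag(g)


class TestDensity:
    def test_complete_directed_triangle(self, directed_triangle):
        assert density(directed_triangle) == 1.0

    def test_undefined_below_two_nodes(self):
        with pytest.raises(ValueError):
            density(make_lag([], nodes=["a"]))


class TestNodeClustering:
    def test_triangle_vertices_fully_clustered(self, directed_triangle):
        for v in "abc":
            c = node_clustering(directed_triangle, v)
            assert (c.k, c.r, c.value) == (2, 2, 1.0)

    def test_star_centre_has_empty_neighbourhood_subgraph(self):
        lag = make_lag([("hub", f"leaf{i}") for i in range(4)])
        c = node_clustering(lag, "hub")
        assert (c.k, c.r, c.value) == (4, 0, 0.0)

    def test_neighbourhood_is_union_of_in_and_out(self):
        # A->B, B->C, A->C, C->A: B's neighbourhood {A, C} has both A->C, C->A
        lag = make_lag([("A", "B"), ("B", "C"), ("A", "C"), ("C", "A")])
        c = node_clustering(lag, "B")
        assert (c.k, c.r, c.value) == (2, 2, 1.0)

    def test_low_degree_nodes_count_zero(self):
        lag = make_lag([("a", "b")])
        assert node_clustering(lag, "a").value == 0.0

    def test_unknown_word_raises(self, directed_triangle):
        with pytest.raises(KeyError):
            node_clustering(directed_triangle, "zebra")

    def test_mean_over_triangle_is_one(self, directed_triangle):
        assert mean_clustering(directed_triangle) == 1.0

    def test_mean_exclude_low_degree_flag(self):
        lag = make_lag([(a, b) for a in "abc" for b in "abc" if a != b] + [("a", "d")])
        incl = mean_clustering(lag)
        excl = mean_clustering(lag, include_low_degree=False)
        assert excl > incl  # d has a single neighbour and drags the mean down

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            lag = random_digraph(int(rng.integers(3, 9)), rng.uniform(0.1, 0.8), rng)
            nodes, a = adjacency(lag)
            for i, v in enumerate(nodes):
                assert node_clustering(lag, v).value == pytest.approx(
                    clustering_oracle(a, i)
                )


class TestPathStats:
    def test_directed_cycle_closed_form(self):
        lag = make_lag([(i, (i + 1) % 5) for i in range(5)])
        ps = path_stats(lag)
        assert ps.diameter == 4
        assert ps.avg_shortest_path == pytest.approx(2.5)
        assert all(e == 4 for e in ps.eccentricity.values())
        assert ps.reachable_pair_fraction == 1.0

    def test_two_disjoint_edges(self):
        lag = make_lag([("a", "b"), ("c", "d")])
        ps = path_stats(lag)
        assert ps.diameter == 1
        assert ps.reachable_pair_fraction == pytest.approx(2 / 12)
        assert ps.eccentricity["b"] == 0  # reaches nothing

    def test_undirected_mode_symmetrizes(self):
        lag = make_lag([("a", "b"), ("b", "c")])
        assert path_stats(lag, "undirected").reachable_pair_fraction == 1.0
        assert path_stats(lag).reachable_pair_fraction == pytest.approx(3 / 6)

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            lag = random_digraph(10, rng.uniform(0.1, 0.5), rng)
            nodes, a = adjacency(lag)
            d = floyd_warshall(a)
            finite = d[np.isfinite(d) & (d > 0)]
            ps = path_stats(lag)
            if finite.size:
                assert ps.avg_shortest_path == pytest.approx(finite.mean())
                assert ps.diameter == int(finite.max())

    def test_adding_an_edge_never_lengthens_paths(self):
        rng = np.random.default_rng(3)
        lag = random_digraph(8, 0.25, rng)
        nodes, a = adjacency(lag)
        d_before = floyd_warshall(a)
        free = [(u, v) for u in lag.graph for v in lag.graph
                if u != v and not lag.graph.has_edge(u, v)]
        u, v = free[0]
        lag.graph.add_edge(u, v, weight=1)
        _, a2 = adjacency(lag, order=nodes)
        assert np.all(floyd_warshall(a2) <= d_before)


class TestCentralities:
    def test_triangle_is_fully_symmetric(self, directed_triangle):
        table = centralities(directed_triangle)
        assert (table.nunique() == 1).all()

    def test_path_betweenness(self):
        table = centralities(make_lag([("A", "B"), ("B", "C")]))
        assert table.loc["B", "betweenness"] == 1.0
        assert table.loc["A", "betweenness"] == 0.0
        assert table.loc["C", "betweenness"] == 0.0

    def test_hub_maximal_on_every_measure(self):
        spokes = [f"s{i}" for i in range(5)]
        lag = make_lag(
            [("hub", s) for s in spokes]
            + [(s, "hub") for s in spokes]
            + [("s0", "s1")]
        )
        table = centralities(lag)
        for measure in ("degree", "weighted_degree", "closeness",
                        "harmonic_closeness", "betweenness"):
            assert table[measure].idxmax() == "hub"
        assert table["eccentricity"].idxmin() == "hub"

    def test_weighted_degree_sums_weights(self):
        lag = make_lag([("a", "b", 3), ("b", "a", 2), ("b", "c", 1)])
        table = centralities(lag)
        assert table.loc["b", "degree"] == 3
        assert table.loc["b", "weighted_degree"] == 6


class TestRanking:
    def test_ties_break_lexicographically(self):
        table = centralities(make_lag([(a, b) for a in "abc" for b in "abc" if a != b]))
        assert top_central(table, "degree", 3) == ["a", "b", "c"]

    def test_degree_ranks_descending(self):
        lag = make_lag([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")])
        assert top_central(centralities(lag), "degree", 2) == ["a", "b"]

    def test_eccentricity_ranks_ascending(self):
        # chain a->b->c: eccentricities a=2, b=1, c=0
        table = centralities(make_lag([("a", "b"), ("b", "c")]))
        assert top_central(table, "eccentricity", 1, min_value=1) == ["b"]

    def test_min_value_filter(self):
        lag = make_lag([("a", "b"), ("a", "c")])
        ranked = top_central(centralities(lag), "degree", 5, min_value=2)
        assert ranked == ["a"]

    def test_unknown_measure_raises(self, directed_triangle):
        with pytest.raises(KeyError):
            top_central(centralities(directed_triangle), "pagerank", 3)

    @pytest.mark.parametrize(
        "a,b,count,jaccard",
        [
            (list("abcdefghij"), list("abcdefghij"), 10, 1.0),
            (list("abc"), list("xyz"), 0, 0.0),
            (list("abcdefghij"), list("abcdefgh") + list("xyzuv"), 8, 8 / 15),
        ],
    )
    def test_ranking_overlap(self, a, b, count, jaccard):
        assert ranking_overlap(a, b) == (count, pytest.approx(jaccard))


def test_summary_invariants_on_random_graph():
    rng = np.random.default_rng(5)
    lag = random_digraph(12, 0.3, rng)
    s = summarize(lag)
    assert 0 <= s.density <= 1
    assert 0 <= s.mean_clustering <= 1
    assert s.diameter >= s.avg_shortest_path or s.reachable_pair_fraction == 0
    assert math.isclose(s.density, lag.edge_count / (12 * 11))
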