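import math

import networkx as nx
import numpy as np
import pytest

from pecnet.topology import (characteristic_path_length,
                             clustering_coefficient, global_efficiency,
                             graph_metrics, is_connected, local_efficiency,
                             randomize_degree_preserving, small_worldness,
                             threshold_proportional)

from _oracles import (bfs_distances, brute_L, brute_cc, brute_eglobal,
                      brute_elocal)


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


# -- worked examples ---------------------------------------------------------


class TestWorkedExamples:
    def test_triangle_fully_clustered(self):
        k3 = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert clustering_coefficient(k3) == 1.0

    def test_star_has_no_triangles(self):
        star = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert clustering_coefficient(star) == 0.0
        assert local_efficiency(star) == 0.0

    def test_chorded_square_clustering(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        assert clustering_coefficient(g) == pytest.approx(5 / 6)
        assert local_efficiency(g) == pytest.approx(brute_elocal(g))

    def test_path_graph_metrics(self):
        path = graph_from_edges(3, [(0, 1), (1, 2)])
        L, unreach = characteristic_path_length(path)
        assert L == pytest.approx(4 / 3)
        assert unreach == 0.0
        assert global_efficiency(path) == pytest.approx(5 / 6)

    def test_complete_graph_metrics(self):
        k5 = 1 - np.eye(5, dtype=np.int8)
        assert characteristic_path_length(k5)[0] == 1.0
        assert global_efficiency(k5) == 1.0

    def test_k4_local_efficiency_is_one(self):
        k4 = 1 - np.eye(4, dtype=np.int8)
        assert local_efficiency(k4) == pytest.approx(1.0)

    def test_two_disconnected_edges(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        L, unreach = characteristic_path_length(g)
        assert L == 1.0
        assert unreach == pytest.approx(2 / 3)

    def test_empty_graph_efficiency_zero(self):
        assert global_efficiency(np.zeros((4, 4), dtype=np.int8)) == 0.0


class TestThreshold:
    def test_68_nodes_top_10_percent_is_228_edges(self, rng):
        w = rng.uniform(0, 1, (68, 68))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        adj = threshold_proportional(w, 0.10)
        assert adj.sum() // 2 == math.ceil(0.10 * 2278) == 228

    def test_four_nodes_keeps_single_largest(self, rng):
        w = np.zeros((4, 4))
        w[0, 3] = w[3, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.5
        adj = threshold_proportional(w, 0.10)
        assert adj.sum() == 2 and adj[0, 3] == 1

    def test_density_one_gives_complete_graph(self, rng):
        w = rng.uniform(0, 1, (6, 6))
        w = (w + w.T) / 2
        adj = threshold_proportional(w, 1.0)
        assert adj.sum() == 6 * 5

    def test_tied_weights_still_deterministic(self):
        w = np.ones((5, 5))
        a = threshold_proportional(w, 0.3)
        b = threshold_proportional(w, 0.3)
        assert np.array_equal(a, b)
        assert a.sum() // 2 == math.ceil(0.3 * 10)


def test_metrics_match_brute_force_on_random_graphs(rng):
    """Implementation vs exhaustive BFS/triangle oracle on small graphs,
    cross-checked against networkx."""
    for trial in range(60):
        n = int(rng.integers(3, 8))
        p = rng.uniform(0.3, 0.9)
        a = (rng.uniform(size=(n, n)) < p).astype(np.int8)
        a = np.triu(a, 1)
        a = a | a.T
        assert clustering_coefficient(a) == pytest.approx(brute_cc(a), abs=1e-12)
        assert global_efficiency(a) == pytest.approx(brute_eglobal(a), abs=1e-12)
        assert local_efficiency(a) == pytest.approx(brute_elocal(a), abs=1e-12)
        if a.sum() > 0:
            L, unreach = characteristic_path_length(a)
            bl, bu = brute_L(a)
            assert L == pytest.approx(bl, abs=1e-12)
            assert unreach == pytest.approx(bu, abs=1e-12)
        g = nx.from_numpy_array(a)
        assert clustering_coefficient(a) == pytest.approx(
            nx.average_clustering(g), abs=1e-12)
        assert global_efficiency(a) == pytest.approx(
            nx.global_efficiency(g), abs=1e-12)


@pytest.fixture(scope="module")
def base_graph():
    g = nx.erdos_renyi_graph(30, 0.25, seed=4)
    while not nx.is_connected(g):
        g = nx.erdos_renyi_graph(30, 0.25, seed=5)
    return nx.to_numpy_array(g, dtype=np.int8)


class TestRandomization:
    def test_degree_sequence_preserved(self, base_graph):
        ens = randomize_degree_preserving(base_graph, n=10, seed=0)
        for m in ens:
            assert np.array_equal(m.sum(axis=1), base_graph.sum(axis=1))

    def test_members_connected(self, base_graph):
        ens = randomize_degree_preserving(base_graph, n=10, seed=1)
        assert all(is_connected(m) for m in ens)

    def test_mixing_jaccard_below_070(self, rng):
        w = rng.uniform(0, 1, (68, 68))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        adj = threshold_proportional(w, 0.10)
        if not is_connected(adj):  # density 10% on uniform weights: connected
            pytest.skip("base graph disconnected for this draw")
        base_edges = {frozenset(e) for e in zip(*np.nonzero(np.triu(adj, 1)))}
        overlaps = []
        for seed in range(20):
            m = randomize_degree_preserving(adj, n=1, seed=seed)[0]
            edges = {frozenset(e) for e in zip(*np.nonzero(np.triu(m, 1)))}
            inter = len(base_edges & edges)
            overlaps.append(inter / len(base_edges | edges))
        assert np.mean(overlaps) < 0.7

    def test_tiny_graph_returns_copies(self):
        a = graph_from_edges(2, [(0, 1)])
        ens = randomize_degree_preserving(a, n=3, seed=0)
        assert all(np.array_equal(m, a) for m in ens)


class TestSmallWorldness:
    def test_self_ensemble_gives_sigma_one(self):
        g = nx.to_numpy_array(nx.erdos_renyi_graph(20, 0.4, seed=0),
                              dtype=np.int8)
        m = small_worldness(g, [g.copy(), g.copy()])
        assert m.sigma == 1.0

    def test_watts_strogatz_is_small_world(self):
        g = nx.to_numpy_array(nx.watts_strogatz_graph(68, 6, 0.1, seed=3),
                              dtype=np.int8)
        m = small_worldness(g, randomize_degree_preserving(g, n=20, seed=0))
        assert m.sigma > 1.5


class TestInvariantsAndProperties:
    def test_eglobal_at_least_inverse_path_length(self, rng):
        """Jensen: the mean of 1/d is at least 1/(mean of d)."""
        for seed in range(20):
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            if not nx.is_connected(g):
                continue
            a = nx.to_numpy_array(g, dtype=np.int8)
            L, _ = characteristic_path_length(a)
            assert global_efficiency(a) >= 1.0 / L - 1e-12

    def test_adding_edge_never_decreases_eglobal(self, rng):
        for seed in range(20):
            a = nx.to_numpy_array(nx.gnp_random_graph(10, 0.3, seed=seed),
                                  dtype=np.int8)
            before = global_efficiency(a)
            empty = np.argwhere(np.triu(1 - a, 1))
            if len(empty) == 0:
                continue
            i, j = empty[seed % len(empty)]
            a[i, j] = a[j, i] = 1
            assert global_efficiency(a) >= before - 1e-12

    def test_graph_metrics_end_to_end(self, rng):
        w = rng.uniform(0, 1, (40, 40))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        m = graph_metrics(w, density=0.2, n_random=10, seed=0)
        assert 0 <= m.CC <= 1
        assert 0 <= m.Eglobal <= 1
        assert 0 <= m.Elocal <= 1
        assert m.L >= 1
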