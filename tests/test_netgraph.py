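"""Weighted graph efficiency: hand-computed cases, exhaustive-path
oracles, null-model invariants, and AUC summaries."""

import itertools

import networkx as nx
import numpy as np
import pytest

from tremornet.netgraph import (
    RoiNetwork,
    WeightedGraph,
    default_sparsity_grid,
    efficiency_curve,
    generate_null_ensemble,
    global_efficiency,
    local_efficiency,
    metric_auc,
    normalized_efficiency,
    roi_correlation_matrix,
    small_world_flag,
    sparsity_threshold,
)


def exhaustive_shortest_paths(adj: np.ndarray) -> np.ndarray:
    """Oracle: minimum of sum(1/w) over every simple path, by enumeration."""
    n = adj.shape[0]
    g = nx.from_numpy_array(adj)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            best = np.inf
            for path in nx.all_simple_paths(g, i, j):
                length = sum(1.0 / adj[a, b] for a, b in zip(path, path[1:]))
                best = min(best, length)
            d[i, j] = d[j, i] = best
    return d


def exhaustive_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = exhaustive_shortest_paths(adj)
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return inv.sum() / (n * (n - 1))


def exhaustive_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        if nbrs.size >= 2:
            total += exhaustive_global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return total / n


def random_weighted_graph(rng, n, p=0.4):
    adj = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            adj[i, j] = adj[j, i] = rng.uniform(0.2, 1.0)
    return adj


class TestRoiCorrelation:
    def test_duplicated_series_give_unit_offdiagonal(self, rng):
        x = rng.standard_normal((3, 50))
        x[1] = x[0]
        net = roi_correlation_matrix(x)
        assert net.corr[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(net.corr), 1.0)

    def test_matches_pairwise_pearson_oracle(self, rng):
        x = rng.standard_normal((5, 80))
        net = roi_correlation_matrix(x)
        for i in range(5):
            for j in range(5):
                assert net.corr[i, j] == pytest.approx(np.corrcoef(x[i], x[j])[0, 1], abs=1e-12)

    def test_constant_series_rejected_by_name(self, rng):
        x = rng.standard_normal((4, 30))
        x[2] = 1.0
        with pytest.raises(ValueError, match="regionC"):
            roi_correlation_matrix(x, labels=["regionA", "regionB", "regionC", "regionD"])


class TestSparsityThreshold:
    def test_edge_count_n5_half(self, rng):
        net = RoiNetwork(corr=np.abs(np.corrcoef(rng.standard_normal((5, 40)))))
        g = sparsity_threshold(net, 0.5)
        assert g.n_edges == 5  # round(0.5 * 10)

    def test_full_sparsity_reproduces_positive_matrix(self, rng):
        c = np.abs(np.corrcoef(rng.standard_normal((5, 40))))
        net = RoiNetwork(corr=c)
        g = sparsity_threshold(net, 1.0)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(g.adjacency[off], net.corr[off])

    def test_nesting_across_grid(self, rng):
        net = roi_correlation_matrix(rng.standard_normal((10, 60)))
        prev = set()
        for s in default_sparsity_grid():
            g = sparsity_threshold(net, float(s))
            edges = {(i, j) for i, j, _ in g.edge_list()}
            assert prev.issubset(edges)
            prev = edges

    def test_too_few_positive_correlations_warns(self):
        c = -0.5 * np.ones((4, 4))
        c[0, 1] = c[1, 0] = 0.8
        np.fill_diagonal(c, 1.0)
        with pytest.warns(UserWarning, match="positive"):
            g = sparsity_threshold(RoiNetwork(corr=c), 0.9)
        assert g.n_edges == 1


class TestEfficiency:
    def test_complete_unit_graph(self):
        adj = np.ones((4, 4)) - np.eye(4)
        assert global_efficiency(adj) == pytest.approx(1.0)

    def test_edgeless_graph(self):
        assert global_efficiency(np.zeros((5, 5))) == 0.0

    def test_two_edge_path_hand_dijkstra(self):
        # A-B and B-C at weight 0.5: d = 2, 2, 4 -> E = (4*(1/2)+2*(1/4))/6
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 0.5
        adj[1, 2] = adj[2, 1] = 0.5
        assert global_efficiency(adj) == pytest.approx(5.0 / 12.0)

    def test_unit_triangle_local(self):
        adj = np.ones((3, 3)) - np.eye(3)
        assert local_efficiency(adj) == pytest.approx(1.0)

    def test_star_graph_local_zero(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = adj[1:, 0] = 1.0
        assert local_efficiency(adj) == 0.0

    def test_weighted_toy_matches_subgraph_oracle(self, rng):
        adj = random_weighted_graph(rng, 6, p=0.6)
        assert local_efficiency(adj) == pytest.approx(exhaustive_local_efficiency(adj), abs=1e-12)

    def test_unit_weights_match_binary_networkx(self, rng):
        adj = (random_weighted_graph(rng, 7, p=0.5) > 0).astype(float)
        g = nx.from_numpy_array(adj)
        assert global_efficiency(adj) == pytest.approx(nx.global_efficiency(g), abs=1e-12)

    def test_eglob_nondecreasing_in_sparsity(self, rng):
        net = roi_correlation_matrix(rng.standard_normal((10, 60)))
        eg = [global_efficiency(sparsity_threshold(net, float(s))) for s in default_sparsity_grid()]
        assert (np.diff(eg) >= -1e-12).all()


class TestNullEnsemble:
    def test_degree_sequence_and_counts_preserved(self, rng):
        adj = random_weighted_graph(rng, 10, p=0.4)
        g = WeightedGraph(adjacency=adj, sparsity=0.4)
        for null in generate_null_ensemble(g, n_null=10, seed=1):
            assert null.n_nodes == g.n_nodes
            assert null.n_edges == g.n_edges
            assert np.array_equal(null.degree_sequence(), g.degree_sequence())

    def test_weights_travel_with_edges(self, rng):
        adj = random_weighted_graph(rng, 8, p=0.5)
        g = WeightedGraph(adjacency=adj, sparsity=0.5)
        ws = np.sort([w for _, _, w in g.edge_list()])
        for null in generate_null_ensemble(g, n_null=5, seed=2):
            assert np.allclose(np.sort([w for _, _, w in null.edge_list()]), ws)

    def test_deterministic_given_seed(self, rng):
        adj = random_weighted_graph(rng, 8, p=0.5)
        g = WeightedGraph(adjacency=adj, sparsity=0.5)
        a = generate_null_ensemble(g, n_null=3, seed=7)
        b = generate_null_ensemble(g, n_null=3, seed=7)
        assert all(np.array_equal(x.adjacency, y.adjacency) for x, y in zip(a, b))

    def test_ring_lattice_nulls_gain_global_efficiency(self):
        # rewiring a ring lattice introduces shortcuts, raising E_glob
        n = 20
        adj = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                j = (i + d) % n
                adj[i, j] = adj[j, i] = 1.0
        g = WeightedGraph(adjacency=adj, sparsity=2 * n / (n * (n - 1) / 2))
        e_real = global_efficiency(g)
        nulls = generate_null_ensemble(g, n_null=100, seed=3)
        e_null = np.mean([global_efficiency(x) for x in nulls])
        assert e_null > e_real


class TestNormalization:
    def test_self_normalization_is_unity(self):
        real = np.array([0.25, 0.5, 1.0])  # dyadic: ratios are exactly 1
        null = np.tile(real, (10, 1))
        ratio, ok = normalized_efficiency(real, null)
        assert np.allclose(ratio, 1.0)
        assert ok.all()
        # e_loc_norm == 1 fails the strict "> 1" small-world requirement
        assert not small_world_flag(ratio, ratio)

    def test_modular_network_is_small_world(self, rng):
        # two dense modules joined by one bridge: strong clustering with
        # short paths -> normalised local efficiency above 1
        n = 12
        adj = np.zeros((n, n))
        for block in (range(0, 6), range(6, 12)):
            for i, j in itertools.combinations(block, 2):
                adj[i, j] = adj[j, i] = rng.uniform(0.6, 1.0)
        adj[5, 6] = adj[6, 5] = 0.8
        g = WeightedGraph(adjacency=adj, sparsity=(2 * 15 + 1) / 66)
        nulls = generate_null_ensemble(g, n_null=50, seed=4)
        el_ratio = local_efficiency(g) / np.mean([local_efficiency(x) for x in nulls])
        assert el_ratio > 1.0

    def test_zero_null_mean_excluded(self):
        real = np.array([0.5, 0.5])
        null = np.array([[0.5, 0.0], [0.5, 0.0]])
        with pytest.warns(UserWarning, match="zero null-mean"):
            ratio, ok = normalized_efficiency(real, null)
        assert np.isnan(ratio[1]) and ok[0] and not ok[1]


class TestMetricAuc:
    def test_constant_curve(self):
        grid = default_sparsity_grid()
        assert metric_auc(grid, np.full(grid.size, 2.0)) == pytest.approx(0.52 * 2.0)

    def test_triangle(self):
        assert metric_auc(np.array([0.08, 0.6]), np.array([0.0, 1.0])) == pytest.approx(0.26)

    def test_matches_independent_trapezoid(self, rng):
        s = default_sparsity_grid()
        v = rng.standard_normal(s.size)
        expected = sum((s[i + 1] - s[i]) * (v[i] + v[i + 1]) / 2 for i in range(s.size - 1))
        assert metric_auc(s, v) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            metric_auc(np.array([0.1, 0.2]), np.array([1.0]))


def test_efficiency_curve_end_to_end(rng):
    net = roi_correlation_matrix(rng.standard_normal((8, 120)))
    curve = efficiency_curve(net, n_null=10, seed=5)
    assert curve.sparsities.size == 27
    assert curve.auc_glob == pytest.approx(metric_auc(curve.sparsities, curve.e_glob))
    assert (curve.e_glob >= 0).all() and (curve.e_loc >= 0).all()
    assert curve.small_world in (True, False)
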