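import math

import numpy as np
import pytest

import oracles
from fctopo import (
    MetricCurve,
    auc_over_sparsity,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    make_toy_graph,
    nodal_degree,
    nodal_efficiency,
    nodal_path_length,
    shortest_path_lengths,
)
from fctopo.metrics import GraphMetricsAUC, auc_table, graph_metric_table, sweep_metrics


class TestClosedForms:
    def test_complete_graph(self):
        g = make_toy_graph("complete", 5)
        assert np.all(nodal_degree(g) == 4)
        assert np.all(clustering_coefficient(g) == 1.0)
        assert characteristic_path_length(g) == 1.0
        assert global_efficiency(g) == pytest.approx(1.0)
        assert np.all(nodal_path_length(g) == 1.0)
        assert np.all(nodal_efficiency(g) == pytest.approx(1.0))
        assert np.all(betweenness_centrality(g) == 0.0)

    def test_star(self, star5):
        assert sorted(nodal_degree(star5).tolist()) == [1, 1, 1, 1, 4]
        assert np.all(clustering_coefficient(star5) == 0.0)
        assert np.all(local_efficiency(star5) == 0.0)

    def test_path_p3(self, p3):
        d = shortest_path_lengths(p3)
        np.testing.assert_array_equal(d, [[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        assert characteristic_path_length(p3) == pytest.approx(4 / 3)
        assert global_efficiency(p3) == pytest.approx(5 / 6)
        np.testing.assert_allclose(nodal_path_length(p3), [1.5, 1.0, 1.5])
        np.testing.assert_allclose(betweenness_centrality(p3), [0.0, 1.0, 0.0])

    def test_triangle_local_efficiency(self, triangle):
        np.testing.assert_allclose(local_efficiency(triangle), 1.0)
        np.testing.assert_allclose(clustering_coefficient(triangle), 1.0)

    def test_disconnected_components_unreachable(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        d = shortest_path_lengths(a)
        assert math.isinf(d[0, 2]) and math.isinf(d[1, 3])
        assert characteristic_path_length(a) == 1.0  # reachable pairs only
        assert global_efficiency(a) == pytest.approx((4 * 1.0) / 12)

    def test_empty_graph_conventions(self):
        a = np.zeros((3, 3), dtype=np.uint8)
        assert global_efficiency(a) == 0.0
        with pytest.raises(ValueError, match="no reachable"):
            characteristic_path_length(a)
        assert np.all(np.isnan(nodal_path_length(a)))


class TestOracleAgreement:
    def test_exhaustive_labeled_graphs_up_to_4_nodes(self):
        for n in (2, 3, 4):
            for a in oracles.all_labeled_graphs(n):
                _assert_all_metrics_match(a)

    def test_random_graphs_match_bruteforce(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 9))
            g = make_toy_graph("erdos_renyi", n, p=float(rng.uniform(0.2, 0.7)),
                               seed=int(rng.integers(2**31)))
            _assert_all_metrics_match(g.adjacency)

    def test_watts_strogatz_distances_match_bfs(self):
        g = make_toy_graph("watts_strogatz", 30, k=4, p=0.2, seed=5)
        np.testing.assert_allclose(shortest_path_lengths(g),
                                   oracles.bfs_distances(g.adjacency))

    def test_er_degrees_are_row_sums(self):
        g = make_toy_graph("erdos_renyi", 20, m=40, seed=3)
        np.testing.assert_array_equal(nodal_degree(g), g.adjacency.sum(axis=1))

    def test_betweenness_matches_path_enumeration_n10(self):
        g = make_toy_graph("erdos_renyi", 10, p=0.35, seed=12)
        np.testing.assert_allclose(betweenness_centrality(g),
                                   oracles.betweenness(g.adjacency), atol=1e-12)


def _assert_all_metrics_match(a):
    if a.sum() == 0:
        return
    np.testing.assert_array_equal(nodal_degree(a), oracles.degree(a))
    np.testing.assert_allclose(clustering_coefficient(a), oracles.clustering(a),
                               atol=1e-12)
    np.testing.assert_allclose(shortest_path_lengths(a), oracles.bfs_distances(a))
    np.testing.assert_allclose(global_efficiency(a), oracles.global_efficiency(a),
                               atol=1e-12)
    np.testing.assert_allclose(local_efficiency(a), oracles.local_efficiency(a),
                               atol=1e-12)
    np.testing.assert_allclose(nodal_path_length(a), oracles.nodal_path_length(a),
                               atol=1e-12)
    np.testing.assert_allclose(nodal_efficiency(a), oracles.nodal_efficiency(a),
                               atol=1e-12)
    np.testing.assert_allclose(betweenness_centrality(a), oracles.betweenness(a),
                               atol=1e-12)
    try:
        ours = characteristic_path_length(a)
    except ValueError:
        return
    np.testing.assert_allclose(ours, oracles.characteristic_path_length(a),
                               atol=1e-12)


class TestInvariants:
    def test_nodal_efficiency_mean_equals_global(self, random_graphs):
        for g in random_graphs:
            assert nodal_efficiency(g).mean() == pytest.approx(
                global_efficiency(g), abs=1e-12)

    def test_efficiency_jensen_bound_on_connected(self, random_graphs):
        for g in random_graphs:
            d = shortest_path_lengths(g)
            if np.isinf(d).any():
                continue
            assert global_efficiency(g) >= 1.0 / characteristic_path_length(g) - 1e-12

    def test_edge_addition_monotonicity(self, rng):
        g = make_toy_graph("erdos_renyi", 12, p=0.25, seed=21)
        a = g.adjacency.copy()
        zeros = np.argwhere(np.triu(a == 0, k=1))
        i, j = zeros[int(rng.integers(len(zeros)))]
        b = a.copy()
        b[i, j] = b[j, i] = 1
        assert global_efficiency(b) >= global_efficiency(a) - 1e-12
        assert np.all(nodal_degree(b) >= nodal_degree(a))

    def test_node_relabeling_equivariance(self):
        g = make_toy_graph("erdos_renyi", 9, p=0.4, seed=2)
        perm = np.random.default_rng(0).permutation(9)
        ap = g.adjacency[np.ix_(perm, perm)]
        for fn in (nodal_degree, clustering_coefficient, local_efficiency,
                   nodal_efficiency, betweenness_centrality):
            np.testing.assert_allclose(fn(ap), fn(g.adjacency)[perm], atol=1e-12)


class TestAUC:
    def test_constant_curve(self):
        s = np.linspace(0.10, 0.50, 41)
        auc = auc_over_sparsity(MetricCurve("m", "GLOBAL", s, np.full(41, 2.5)))
        assert auc.auc == pytest.approx(0.4 * 2.5, abs=1e-12)

    def test_linear_ramp_triangle_area(self):
        s = np.linspace(0.10, 0.50, 41)
        v = np.linspace(0.0, 1.0, 41)
        assert auc_over_sparsity(MetricCurve("m", "GLOBAL", s, v)).auc == pytest.approx(0.2)

    def test_random_curve_matches_trapezoid_sum(self, rng):
        s = np.linspace(0.10, 0.50, 41)
        v = np.random.default_rng(3).normal(size=41)
        assert auc_over_sparsity(MetricCurve("m", "n", s, v)).auc == pytest.approx(
            oracles.trapezoid_auc(s, v), abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 finite points"):
            auc_over_sparsity(MetricCurve("m", "n", np.array([0.1]), np.array([1.0])))

    def test_nan_points_dropped_pairwise(self):
        s = np.array([0.1, 0.2, 0.3])
        v = np.array([1.0, np.nan, 1.0])
        assert auc_over_sparsity(MetricCurve("m", "n", s, v)).auc == pytest.approx(0.2)


def test_sweep_tables_and_transformer(small_study):
    import fctopo

    _, panels, _ = small_study
    z = fctopo.PearsonConnectivity().fit(panels[:3]).transform(panels[:3])
    sweeps = fctopo.ProportionalThresholdSweep(lo=0.2, hi=0.4, step=0.1).fit(z).transform(z)
    long = sweep_metrics(sweeps[0], panels[0].region_names, subject_id="a")
    assert set(long.columns) == {"subject", "sparsity", "metric", "node", "value"}
    aucs = auc_table(long)
    assert (aucs["subject"] == "a").all()
    wide = GraphMetricsAUC().fit(sweeps).transform(sweeps)
    assert wide.shape[0] == 3
    assert any(c.startswith("global_efficiency|GLOBAL") for c in wide.columns)
    # AUC of the global-efficiency curve recomputed by hand for one subject
    geff = long[(long.metric == "global_efficiency") & (long.node == "GLOBAL")]
    manual = oracles.trapezoid_auc(geff["sparsity"].to_numpy(), geff["value"].to_numpy())
    got = aucs[(aucs.metric == "global_efficiency") & (aucs.node == "GLOBAL")]["auc"].iloc[0]
    assert got == pytest.approx(manual, abs=1e-12)
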