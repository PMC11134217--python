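"""Graph metrics: thresholding, segregation/integration measures, AUC."""

import numpy as np
import pytest

from neoconn import reference as R
from neoconn.core import ConnectivityMatrix, MetricCurve
from neoconn.metrics import (
    GLOBAL_METRICS,
    characteristic_path_length,
    clustering_coefficient,
    default_density_grid,
    draw_null_networks,
    global_efficiency,
    local_efficiency,
    metric_auc,
    metric_curves,
    modularity,
    modularity_value,
    null_network,
    proportional_threshold,
    shortest_path_matrix,
    small_worldness,
    transitivity,
)

from conftest import net_from, random_net


def conn_from(values, labels=None, mode="abs_r"):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = [f"r{i}" for i in range(values.shape[0])]
    return ConnectivityMatrix(mode, values, labels)


def triangle(w=1.0):
    return net_from([[0, w, w], [w, 0, w], [w, w, 0]])


def star(n=5):
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    return net_from(w)


def chain3():
    # path a-b-c with weights 0.5 and 0.25; max-normalised lengths 2 and 4
    return net_from([[0, 0.5, 0], [0.5, 0, 0.25], [0, 0.25, 0]])


def complete(n, w=1.0):
    m = np.full((n, n), w)
    np.fill_diagonal(m, 0.0)
    return net_from(m)


def ring_lattice(n=24, k=3):
    """Ring lattice with distance-decaying weights (a small-world substrate)."""
    w = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k + 1):
            j = (i + d) % n
            w[i, j] = w[j, i] = 1.0 / d
    return net_from(w)


class TestProportionalThreshold:
    def test_density_one_keeps_everything(self, rng):
        v = rng.random((8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        mat = conn_from(v)
        net = proportional_threshold(mat, 1.0)
        assert np.allclose(net.weights, mat.values)

    def test_92_nodes_at_density_010_has_418_edges(self, rng):
        v = rng.random((92, 92))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        net = proportional_threshold(conn_from(v), 0.10)
        assert net.n_edges == 418  # floor(0.10 * 4186)

    def test_four_node_hand_check(self):
        v = np.array(
            [
                [0, 0.9, 0.1, 0.4],
                [0.9, 0, 0.6, 0.2],
                [0.1, 0.6, 0, 0.8],
                [0.4, 0.2, 0.8, 0],
            ]
        )
        net = proportional_threshold(conn_from(v), 0.5)
        kept = {(0, 1), (2, 3), (1, 2)}  # the 3 largest of 6 edges
        iu, ju = np.triu_indices(4, 1)
        got = {(i, j) for i, j in zip(iu, ju) if net.weights[i, j] > 0}
        assert got == kept
        assert net.weights[0, 1] == 0.9  # weights preserved

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0001])
    def test_invalid_density_rejected(self, bad, rng):
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        with pytest.raises(ValueError):
            proportional_threshold(conn_from(v), bad)

    def test_edge_sets_nested_across_grid(self, rng):
        v = rng.random((20, 20))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        mat = conn_from(v)
        prev = None
        for d in default_density_grid():
            mask = proportional_threshold(mat, float(d)).weights > 0
            if prev is not None:
                assert np.all(mask[prev])  # previous edges still present
            prev = mask

    def test_deterministic_tie_break(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0)
        net1 = proportional_threshold(conn_from(v), 0.5)
        net2 = proportional_threshold(conn_from(v), 0.5)
        assert np.array_equal(net1.weights, net2.weights)
        # ties resolved toward ascending (i, j): (0,1), (0,2), (0,3)
        assert net1.weights[0, 1] > 0 and net1.weights[0, 2] > 0


class TestSegregationMetrics:
    def test_unit_triangle_fully_clustered(self):
        c, mean = clustering_coefficient(triangle())
        assert np.allclose(c, 1.0) and mean == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        c, mean = clustering_coefficient(star())
        assert np.allclose(c, 0.0) and mean == 0.0

    def test_clustering_matches_brute_force(self, rng):
        for _ in range(10):
            net = random_net(rng, 5, 6)
            if net is None:
                continue
            c1, m1 = clustering_coefficient(net)
            c2, m2 = R.clustering_brute(net)
            assert np.allclose(c1, c2, atol=1e-12)
            assert m1 == pytest.approx(m2, abs=1e-12)

    def test_complete_graph_transitivity_one(self):
        assert transitivity(complete(5)) == pytest.approx(1.0)

    def test_edgeless_transitivity_zero(self):
        assert transitivity(net_from(np.zeros((4, 4)))) == 0.0

    def test_transitivity_matches_brute_force(self, rng):
        for _ in range(10):
            net = random_net(rng, 6, 7)
            if net is None:
                continue
            assert transitivity(net) == pytest.approx(
                R.transitivity_brute(net), abs=1e-12
            )

    def test_complete_k4_local_efficiency_one(self):
        e, mean = local_efficiency(complete(4))
        assert np.allclose(e, 1.0) and mean == pytest.approx(1.0)

    def test_star_local_efficiency_zero(self):
        e, _ = local_efficiency(star())
        assert np.allclose(e, 0.0)

    def test_local_efficiency_matches_brute_force(self, rng):
        for _ in range(10):
            net = random_net(rng, 5, 6)
            if net is None:
                continue
            e1, _ = local_efficiency(net)
            e2, _ = R.local_efficiency_brute(net)
            assert np.allclose(e1, e2, atol=1e-12)

    def test_scale_invariance_after_normalisation(self, rng):
        net = random_net(rng, 7, 8)
        scaled = net_from(net.weights * 7.3, net.labels)
        c1, _ = clustering_coefficient(net)
        c2, _ = clustering_coefficient(scaled)
        assert np.allclose(c1, c2, atol=1e-12)
        assert transitivity(net) == pytest.approx(transitivity(scaled), abs=1e-12)
        e1, _ = local_efficiency(net)
        e2, _ = local_efficiency(scaled)
        assert np.allclose(e1, e2, atol=1e-12)
        # path metrics keep the natural weight scale: they scale inversely
        assert global_efficiency(scaled) == pytest.approx(
            7.3 * global_efficiency(net), rel=1e-12
        )


class TestIntegrationMetrics:
    def test_triangle_distances_all_one(self):
        assert np.allclose(
            shortest_path_matrix(triangle()), 1 - np.eye(3)
        )

    def test_chain_distance_adds_inverse_weights(self):
        d = shortest_path_matrix(chain3())
        assert d[0, 2] == pytest.approx(6.0)  # 2 + 4

    def test_disconnected_pairs_infinite(self):
        net = net_from([[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]])
        d = shortest_path_matrix(net)
        assert np.isinf(d[0, 2])

    def test_complete_graph_cpl_one(self):
        assert characteristic_path_length(complete(6)) == pytest.approx(1.0)

    def test_chain_cpl_mean_of_finite(self):
        assert characteristic_path_length(chain3()) == pytest.approx(4.0)

    def test_cpl_reports_infinite_pairs(self):
        net = net_from([[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]])
        value, n_inf = characteristic_path_length(net, return_infinite=True)
        assert value == pytest.approx(1.0)
        assert n_inf == 8

    def test_cpl_decreases_when_nonmaximal_weight_increases(self):
        before = net_from([[0, 1, 0.2], [1, 0, 0.4], [0.2, 0.4, 0]])
        after = net_from([[0, 1, 0.3], [1, 0, 0.4], [0.3, 0.4, 0]])
        assert characteristic_path_length(after) <= characteristic_path_length(
            before
        )

    def test_complete_graph_efficiency_one(self):
        assert global_efficiency(complete(5)) == pytest.approx(1.0)

    def test_edgeless_efficiency_zero(self):
        assert global_efficiency(net_from(np.zeros((3, 3)))) == 0.0

    def test_chain_efficiency_closed_form(self):
        assert global_efficiency(chain3()) == pytest.approx(11 / 36)

    def test_matches_floyd_warshall(self, rng):
        for _ in range(10):
            net = random_net(rng)
            if net is None:
                continue
            assert global_efficiency(net) == pytest.approx(
                R.global_efficiency_brute(net), abs=1e-12
            )


class TestModularity:
    def test_two_cliques_recovered(self):
        w = np.zeros((8, 8))
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        np.fill_diagonal(w, 0.0)
        w[3, 4] = w[4, 3] = 0.05  # weak bridge
        net = net_from(w)
        q, labels = modularity(net, seed=0)
        assert q > 0.3
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[7]
        q_star, _ = R.modularity_exhaustive(net)
        assert q == pytest.approx(q_star, abs=1e-12)

    def test_uniform_complete_graph_never_splits(self):
        net = complete(6)
        q_star, part = R.modularity_exhaustive(net)
        assert q_star == pytest.approx(0.0, abs=1e-12)  # single community wins
        # every nontrivial split scores <= 0
        for labels in ([0, 0, 0, 1, 1, 1], [0, 1, 0, 1, 0, 1]):
            assert modularity_value(net.weights, np.array(labels)) <= 1e-12

    def test_deterministic_given_seed(self, rng):
        net = random_net(rng, 8, 9)
        q1, l1 = modularity(net, seed=123)
        q2, l2 = modularity(net, seed=123)
        assert q1 == q2 and np.array_equal(l1, l2)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            modularity(net_from(np.zeros((3, 3))))


class TestNullModel:
    def test_weight_multiset_and_edge_count_preserved(self, rng):
        net = random_net(rng, 8, 9)
        null = null_network(net, seed=0)
        assert null.n_edges == net.n_edges
        iu, ju = np.triu_indices(net.n_nodes, 1)
        w_in = np.sort(net.weights[iu, ju][net.weights[iu, ju] > 0])
        w_out = np.sort(null.weights[iu, ju][null.weights[iu, ju] > 0])
        assert np.allclose(w_in, w_out)

    def test_degree_preserving_variant(self, rng):
        net = ring_lattice(16, 2)
        null = null_network(net, seed=1, preserve_degree=True)
        assert np.array_equal(
            np.sort((null.weights > 0).sum(axis=1)),
            np.sort((net.weights > 0).sum(axis=1)),
        )

    def test_lattice_more_clustered_than_nulls(self):
        net = ring_lattice()
        _, c_net = clustering_coefficient(net)
        c_nulls = []
        for i in range(200):
            _, c = clustering_coefficient(null_network(net, seed=i))
            c_nulls.append(c)
        assert np.mean(c_nulls) < c_net


class TestSmallWorldness:
    def test_lattice_is_small_world(self):
        assert small_worldness(ring_lattice(), n_null=50, seed=0) > 1.0

    def test_deterministic_given_seed(self):
        net = ring_lattice(16, 2)
        a = small_worldness(net, n_null=20, seed=5)
        b = small_worldness(net, n_null=20, seed=5)
        assert a == b

    def test_explicit_null_sample_route(self):
        net = ring_lattice(16, 2)
        nulls = draw_null_networks(net, n_null=20, seed=5)
        assert small_worldness(net, null_nets=nulls) == small_worldness(
            net, n_null=20, seed=5
        )


class TestAuc:
    def test_constant_curve(self):
        d = default_density_grid()
        curve = MetricCurve("m", d, np.full(d.size, 0.37))
        assert metric_auc(curve) == pytest.approx(0.37)

    def test_linear_curve_exact_trapezoid(self):
        d = default_density_grid()
        curve = MetricCurve("m", d, d.copy())
        assert metric_auc(curve) == pytest.approx(0.225)

    def test_default_grid_has_26_points(self):
        d = default_density_grid()
        assert d.size == 26
        assert d[0] == pytest.approx(0.10) and d[-1] == pytest.approx(0.35)

    def test_single_density_rejected(self):
        with pytest.raises(ValueError):
            metric_auc((np.array([0.1]), np.array([1.0])))

    def test_nodal_curve_gives_per_node_auc(self):
        d = default_density_grid()
        values = np.column_stack([np.full(d.size, 1.0), d])
        auc = metric_auc((d, values))
        assert auc.shape == (2,)
        assert auc[0] == pytest.approx(1.0) and auc[1] == pytest.approx(0.225)


class TestMetricCurves:
    def test_cpl_and_efficiency_move_oppositely(self, rng):
        v = rng.random((20, 20))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        mat = conn_from(v)
        cpl, n_inf, ge = [], [], []
        for d in default_density_grid():
            net = proportional_threshold(mat, float(d))
            value, bad = characteristic_path_length(net, return_infinite=True)
            cpl.append(value)
            n_inf.append(bad)
            ge.append(global_efficiency(net))
        assert np.all(np.diff(ge) >= -1e-12)  # more edges: at least as efficient
        assert cpl[-1] <= cpl[0]  # overall shrinkage with density
        # with an unchanged reachable-pair set, every distance can only drop
        for i in range(len(cpl) - 1):
            if n_inf[i] == n_inf[i + 1]:
                assert cpl[i + 1] <= cpl[i] + 1e-12

    def test_unknown_metric_rejected(self, rng):
        v = rng.random((6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        with pytest.raises(ValueError, match="unknown"):
            metric_curves(conn_from(v), metrics=("betweenness",))

    def test_all_seven_metrics_produce_curves(self, rng):
        v = rng.random((15, 15)) * 0.8
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        d = default_density_grid(0.2, 0.3, 0.05)
        curves, nodal = metric_curves(
            conn_from(v),
            densities=d,
            nodal_metrics=("clustering_coefficient",),
            n_null=10,
            n_restarts=3,
            seed=0,
        )
        assert set(curves) == set(GLOBAL_METRICS)
        for c in curves.values():
            assert c.values.shape == d.shape
            assert np.all(np.isfinite(c.values))
        assert nodal["clustering_coefficient"].values.shape == (d.size, 15)
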