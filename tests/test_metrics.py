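"""Graph measures: closed-form cases, brute-force oracle agreement, scaling."""

import numpy as np
import pytest

import oracles
from docnet.metrics import (
    WeightedGraph,
    auc_over_sparsity,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    degree_centrality,
    eigenvector_centrality,
    global_efficiency,
    local_efficiency,
    network_metrics,
    nodal_clustering,
    nodal_efficiency,
    nodal_local_efficiency,
)


def complete_graph(n, w=1.0):
    W = np.full((n, n), w)
    np.fill_diagonal(W, 0.0)
    return W


class TestClosedFormCases:
    def test_complete_unit_graph(self):
        G = WeightedGraph(complete_graph(5))
        assert global_efficiency(G) == pytest.approx(1.0)
        assert characteristic_path_length(G) == pytest.approx(1.0)
        assert local_efficiency(G) == pytest.approx(1.0)
        assert clustering_coefficient(G) == pytest.approx(1.0)
        for i in range(5):
            assert nodal_efficiency(G, i) == pytest.approx(1.0)
            assert degree_centrality(G, i) == pytest.approx(4.0)
            assert eigenvector_centrality(G, i) == pytest.approx(1 / np.sqrt(5))

    def test_isolated_node(self):
        W = complete_graph(4)
        W[3, :] = W[:, 3] = 0.0
        G = WeightedGraph(W)
        assert nodal_efficiency(G, 3) == 0.0
        assert degree_centrality(G, 3) == 0.0
        assert eigenvector_centrality(G, 3) == 0.0  # outside largest component

    def test_two_node_half_weight_path_length(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert characteristic_path_length(WeightedGraph(W)) == pytest.approx(2.0)

    def test_star_graph_no_clustering(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        G = WeightedGraph(W)
        for i in range(5):
            assert nodal_clustering(G, i) == 0.0

    def test_triangle_unit_clustering(self):
        G = WeightedGraph(complete_graph(3))
        for i in range(3):
            assert nodal_clustering(G, i) == pytest.approx(1.0)

    def test_tree_has_zero_local_efficiency(self):
        W = np.zeros((5, 5))
        for i, j in [(0, 1), (0, 2), (1, 3), (1, 4)]:
            W[i, j] = W[j, i] = 1.0
        assert local_efficiency(WeightedGraph(W)) == 0.0

    def test_path_center_betweenness(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        G = WeightedGraph(W)
        assert betweenness_centrality(G, 1) == pytest.approx(1.0)
        assert betweenness_centrality(G, 0) == 0.0

    def test_empty_graph_efficiency_zero(self):
        assert global_efficiency(np.zeros((0, 0))) == 0.0

    def test_no_reachable_pair_is_error(self):
        with pytest.raises(ValueError, match="reachable"):
            characteristic_path_length(WeightedGraph(np.zeros((3, 3))))


class TestOracleAgreement:
    """All ten measures vs independent brute force on random small graphs."""

    @pytest.mark.parametrize("seed", range(40))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        W = oracles.random_weighted_graph(rng)
        m = network_metrics(W)
        assert m["global_efficiency"] == pytest.approx(
            oracles.global_efficiency(W), abs=1e-9)
        assert m["local_efficiency"] == pytest.approx(
            oracles.nodal_local_efficiency(W).mean(), abs=1e-9)
        assert m["clustering_coefficient"] == pytest.approx(
            oracles.nodal_clustering(W).mean(), abs=1e-9)
        cpl = oracles.characteristic_path_length(W)
        assert m["characteristic_path_length"] == pytest.approx(
            cpl, abs=1e-9, nan_ok=True)
        np.testing.assert_allclose(
            m["nodal_efficiency"], oracles.nodal_efficiency(W), atol=1e-9)
        np.testing.assert_allclose(
            m["nodal_local_efficiency"], oracles.nodal_local_efficiency(W),
            atol=1e-9)
        np.testing.assert_allclose(
            m["nodal_clustering"], oracles.nodal_clustering(W), atol=1e-9)
        np.testing.assert_allclose(
            m["degree_centrality"], oracles.degree_centrality(W), atol=1e-9)
        np.testing.assert_allclose(
            m["betweenness_centrality"], oracles.betweenness_centrality(W),
            atol=1e-9)
        np.testing.assert_allclose(
            m["eigenvector_centrality"], oracles.eigenvector_centrality(W),
            atol=1e-9)


class TestInvariances:
    def test_weight_scaling_behaviour(self, rng):
        W = oracles.random_weighted_graph(rng, n_max=7)
        c = 3.7
        m1, m2 = network_metrics(W), network_metrics(c * W)
        np.testing.assert_allclose(
            m2["nodal_clustering"], m1["nodal_clustering"], atol=1e-12)
        np.testing.assert_allclose(
            m2["eigenvector_centrality"], m1["eigenvector_centrality"], atol=1e-9)
        np.testing.assert_allclose(
            m2["degree_centrality"], c * m1["degree_centrality"], atol=1e-9)
        assert m2["characteristic_path_length"] == pytest.approx(
            m1["characteristic_path_length"] / c)
        assert m2["global_efficiency"] == pytest.approx(
            c * m1["global_efficiency"])
        np.testing.assert_allclose(
            m2["nodal_local_efficiency"], c * m1["nodal_local_efficiency"],
            atol=1e-9)

    def test_permutation_equivariance(self, rng):
        W = oracles.random_weighted_graph(rng)
        n = W.shape[0]
        perm = rng.permutation(n)
        Wp = W[np.ix_(perm, perm)]
        m, mp = network_metrics(W), network_metrics(Wp)
        for name in ("nodal_efficiency", "nodal_clustering", "degree_centrality",
                     "betweenness_centrality", "nodal_local_efficiency"):
            np.testing.assert_allclose(mp[name], m[name][perm], atol=1e-9)

    def test_local_efficiency_subgraph_definition(self, rng):
        W = oracles.random_weighted_graph(rng, n_max=6)
        G = WeightedGraph(W)
        for i in range(W.shape[0]):
            nbrs = np.flatnonzero(W[i] > 0)
            expect = (
                global_efficiency(W[np.ix_(nbrs, nbrs)]) if len(nbrs) >= 2 else 0.0
            )
            assert nodal_local_efficiency(G, i) == pytest.approx(expect)


class TestAUC:
    def test_constant_profile_is_rectangle(self):
        s = np.round(np.arange(0.05, 0.405, 0.01), 10)
        assert auc_over_sparsity(np.full(s.size, 2.5), s) == pytest.approx(
            0.35 * 2.5)

    def test_single_point_degenerate(self):
        assert auc_over_sparsity([3.0], [0.05]) == 0.0

    def test_linear_ramp(self):
        s = np.arange(0.0, 1.01, 0.25)
        assert auc_over_sparsity(s, s) == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            auc_over_sparsity([1.0, 2.0], [0.1])
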