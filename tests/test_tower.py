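"""Correlation networks, graph towers, threshold profiles and consensus."""

import itertools

import numpy as np
import pytest

from fosnet import (
    ActivationTable,
    build_tower,
    consensus_network,
    correlation_network,
    heterogeneity_profile,
    select_threshold,
    threshold_by_density,
)
from fosnet.tower import GraphTower, ThresholdProfile
from fosnet.regions import default_registry

from conftest import make_network


def table_from_counts(counts, treatment="SL", registry=None):
    registry = registry or default_registry()
    counts = np.asarray(counts, dtype=float)
    m, n = counts.shape
    return ActivationTable(
        nodes=registry.all_nodes()[:n],
        specimens=[(f"s{i}", treatment) for i in range(m)],
        counts=counts,
    )


def brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


class TestCorrelationNetwork:
    def test_copy_and_anticorrelation(self):
        base = np.array([1, 2, 3, 4], dtype=float)
        counts = np.column_stack([base, base, (-base + 10)])
        net = correlation_network(table_from_counts(counts), "SL")
        i = {nid: k for k, nid in enumerate(net.node_ids)}
        ids = net.node_ids
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.weights[0, 2] == pytest.approx(-1.0)

    def test_three_node_worked_matrix(self):
        counts = np.array([[1, 2, 4], [2, 4, 3], [3, 6, 2], [4, 8, 1]], dtype=float)
        net = correlation_network(table_from_counts(counts), "SL")
        expected = np.array([[0, 1, -1], [1, 0, -1], [-1, -1, 0]], dtype=float)
        np.testing.assert_allclose(net.weights, expected, atol=1e-12)
        # against the brute-force Pearson formula
        for i, j in itertools.combinations(range(3), 2):
            assert net.weights[i, j] == pytest.approx(
                brute_pearson(counts[:, i], counts[:, j]), abs=1e-12
            )

    def test_constant_node_dropped(self):
        counts = np.array([[1, 5], [2, 5], [3, 5]], dtype=float)
        net = correlation_network(table_from_counts(counts), "SL")
        assert len(net.nodes) == 1

    def test_too_few_specimens(self):
        t = table_from_counts(np.arange(12).reshape(3, 4))
        with pytest.raises(ValueError, match="at least 3"):
            correlation_network(t, "SL", specimen_subset=[0, 1])


class TestBuildTower:
    def test_layer_count(self, rng):
        counts = rng.integers(10, 100, size=(4, 6)).astype(float)
        tower = build_tower(table_from_counts(counts), "SL", m=3)
        assert tower.n_layers == 4

    def test_full_sample_reduces_to_single_network(self, rng):
        counts = rng.integers(10, 100, size=(5, 6)).astype(float)
        t = table_from_counts(counts)
        tower = build_tower(t, "SL", m=5)
        assert tower.n_layers == 1
        full = correlation_network(t, "SL")
        np.testing.assert_allclose(tower.layers[0].weights, full.weights, atol=1e-12)

    def test_jackknife_mean_matches_leave_one_out_oracle(self, rng):
        counts = rng.integers(10, 100, size=(5, 4)).astype(float)
        tower = build_tower(table_from_counts(counts), "SL", m=4)
        mean_w = tower.layer_weights().mean(axis=0)
        # brute force: average the 5 leave-one-out correlations
        for i, j in itertools.combinations(range(4), 2):
            loo = [
                brute_pearson(np.delete(counts[:, i], k), np.delete(counts[:, j], k))
                for k in range(5)
            ]
            assert mean_w[i, j] == pytest.approx(np.mean(loo), abs=1e-12)

    def test_m_out_of_range(self, rng):
        t = table_from_counts(rng.integers(10, 99, size=(4, 4)).astype(float))
        with pytest.raises(ValueError, match="out of range"):
            build_tower(t, "SL", m=2)
        with pytest.raises(ValueError, match="out of range"):
            build_tower(t, "SL", m=5)

    def test_default_is_jackknife(self, rng):
        t = table_from_counts(rng.integers(10, 99, size=(6, 4)).astype(float))
        tower = build_tower(t, "SL")
        assert tower.m == 5 and tower.n_layers == 6


class TestThresholdByDensity:
    def test_extremes(self, nodes30, rng):
        w = rng.normal(size=(6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = make_network(nodes30[:6], w)
        np.testing.assert_array_equal(threshold_by_density(net, 1.0).weights, net.weights)
        assert threshold_by_density(net, 0.0).n_edges == 0

    def test_top_edges_survive(self, nodes30):
        w = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7, (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.1}
        for (i, j), v in vals.items():
            w[i, j] = w[j, i] = v
        net = make_network(nodes30[:4], w)
        thr = threshold_by_density(net, 1 / 3)  # ceil(6/3) = 2 edges
        assert thr.n_edges == 2
        assert thr.weights[0, 1] == 0.9 and thr.weights[0, 2] == 0.8
        assert thr.weights[0, 3] == 0.0

    def test_edge_count_ceiling(self, nodes30, rng):
        w = rng.normal(size=(10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = make_network(nodes30[:10], w)
        for rho in (0.1, 0.25, 0.6):
            assert threshold_by_density(net, rho).n_edges == int(np.ceil(rho * 45))

    def test_signed_ranking_prefers_positive(self, nodes30):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = -0.9
        net = make_network(nodes30[:3], w)
        thr = threshold_by_density(net, 1 / 3)
        assert thr.weights[0, 1] == 0.2 and thr.weights[0, 2] == 0.0
        thr_abs = threshold_by_density(net, 1 / 3, ranking="absolute")
        assert thr_abs.weights[0, 2] == -0.9


def tower_from_layers(nodes, layer_weights):
    layers = [make_network(nodes, w) for w in layer_weights]
    return GraphTower(
        treatment="SL", m=3, nodes=list(nodes), layers=layers,
        combinations=[tuple(range(3))] * len(layers),
    )


class TestHeterogeneityProfile:
    def test_identical_layers_zero_zeta(self, nodes30, rng):
        w = rng.normal(size=(8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        tower = tower_from_layers(nodes30[:8], [w, w, w])
        prof = heterogeneity_profile(tower, np.array([0.1, 0.3, 0.5]))
        np.testing.assert_allclose(prof.zeta, 0.0, atol=1e-15)

    def test_two_layer_hand_computation(self, nodes30):
        # one shared edge with weights 0.5 and 0.7 kept at high density
        w1 = np.zeros((3, 3)); w1[0, 1] = w1[1, 0] = 0.5
        w2 = np.zeros((3, 3)); w2[0, 1] = w2[1, 0] = 0.7
        tower = tower_from_layers(nodes30[:3], [w1, w2])
        prof = heterogeneity_profile(tower, np.array([1.0]))
        assert prof.zeta[0] == pytest.approx(0.1, abs=1e-12)      # population SD
        assert prof.chi_cv[0] == pytest.approx(1 / 6, abs=1e-12)  # 0.1 / 0.6

    def test_efficiency_on_small_graphs(self, nodes30):
        # triangle: Eg = El = 1, J = 2 at rho = 1
        tri = np.zeros((3, 3))
        for i, j in [(0, 1), (1, 2), (0, 2)]:
            tri[i, j] = tri[j, i] = 0.5
        tower = tower_from_layers(nodes30[:3], [tri, tri])
        prof = heterogeneity_profile(tower, np.array([1.0]))
        assert prof.eg[0] == pytest.approx(1.0)
        assert prof.el[0] == pytest.approx(1.0)
        assert prof.j[0] == pytest.approx(2.0)
        # 3-node path: Eg = mean(1, 1, 1/2) = 5/6; El = 0 (no triangles)
        path = np.zeros((3, 3))
        for i, j in [(0, 1), (1, 2)]:
            path[i, j] = path[j, i] = 0.5
        tower_p = tower_from_layers(nodes30[:3], [path, path])
        prof_p = heterogeneity_profile(tower_p, np.array([2 / 3]))
        assert prof_p.eg[0] == pytest.approx(5 / 6)
        assert prof_p.el[0] == pytest.approx(0.0)

    def test_invariant_under_relabeling(self, nodes30, rng):
        ws = []
        for _ in range(3):
            w = rng.normal(size=(7, 7))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            ws.append(w)
        grid = np.array([0.2, 0.5])
        prof = heterogeneity_profile(tower_from_layers(nodes30[:7], ws), grid)
        perm = rng.permutation(7)
        nodes_p = [nodes30[:7][i] for i in perm]
        ws_p = [w[np.ix_(perm, perm)] for w in ws]
        prof_p = heterogeneity_profile(tower_from_layers(nodes_p, ws_p), grid)
        np.testing.assert_allclose(prof.zeta, prof_p.zeta, atol=1e-12)
        np.testing.assert_allclose(prof.chi_cv, prof_p.chi_cv, atol=1e-12)


class TestSelectThreshold:
    @staticmethod
    def _profile(rho, zeta, chi):
        rho = np.asarray(rho, float)
        return ThresholdProfile(
            rho=rho, zeta=np.asarray(zeta, float), chi_cv=np.asarray(chi, float),
            eg=np.zeros_like(rho), el=np.zeros_like(rho), j=np.ones_like(rho) / rho,
        )

    def test_unimodal_chi_flat_zeta(self):
        rho = [0.04, 0.06, 0.08, 0.10, 0.12]
        chi = [0.1, 0.3, 0.9, 0.4, 0.2]
        sel = select_threshold(self._profile(rho, np.zeros(5), chi))
        assert sel.rho0 == 0.08

    def test_flat_profiles_return_smallest(self):
        sel = select_threshold(self._profile([0.05, 0.1, 0.15], np.zeros(3), np.zeros(3)))
        assert sel.rho0 == 0.05
        assert sel.warning is not None

    def test_zeta_constraint_excludes_high_heterogeneity(self):
        rho = [0.05, 0.1, 0.15]
        zeta = [0.0, 0.0, 1.0]
        chi = [0.2, 0.5, 0.9]  # chi peak sits where zeta is large -> excluded
        sel = select_threshold(self._profile(rho, zeta, chi))
        assert sel.rho0 == 0.1

    def test_efficiency_strategy(self):
        prof = self._profile([0.05, 0.1, 0.15], np.zeros(3), [0.1, 0.2, 0.3])
        sel = select_threshold(prof, strategy="efficiency")
        assert sel.rho0 == 0.05  # J = 1/rho is maximal at the smallest density
        assert sel.rho_heterogeneity == 0.15


class TestConsensus:
    def test_single_layer_identity(self, nodes30, rng):
        w = rng.normal(size=(5, 5)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        tower = tower_from_layers(nodes30[:5], [w])
        cons = consensus_network(tower, 0.3)
        thr = threshold_by_density(tower.layers[0], 0.3)
        np.testing.assert_allclose(cons.weights, thr.weights, atol=1e-15)

    def test_shared_edge_mean(self, nodes30):
        w1 = np.zeros((3, 3)); w1[0, 1] = w1[1, 0] = 0.6
        w2 = np.zeros((3, 3)); w2[0, 1] = w2[1, 0] = 0.8
        cons = consensus_network(tower_from_layers(nodes30[:3], [w1, w2]), 1.0)
        assert cons.weights[0, 1] == pytest.approx(0.7)

    def test_absent_as_zero(self, nodes30):
        w1 = np.zeros((3, 3)); w1[0, 1] = w1[1, 0] = 0.8
        zero = np.zeros((3, 3))
        cons = consensus_network(tower_from_layers(nodes30[:3], [w1, zero, zero, zero]), 1.0)
        assert cons.weights[0, 1] == pytest.approx(0.2)
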