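"""Graph metrics against brute-force oracles, networkx, and closed forms."""

import itertools

import networkx as nx
import numpy as np
import pytest

import fnirsnet as fn
from fnirsnet.metrics import nodal_metrics, trapezoid_auc

from conftest import random_binary_graph


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def brute_distances(adj):
    """Floyd-Warshall by triple loop."""
    n = len(adj)
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_ncp(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2) if adj[a, b])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def brute_eg(adj):
    d = brute_distances(adj)
    n = len(adj)
    total = sum(1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
                for i in range(n) for j in range(n) if i != j)
    return total / (n * (n - 1))


def brute_nle(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        out[i] = brute_eg(sub)
    return out


def brute_lp(adj):
    d = brute_distances(adj)
    n = len(adj)
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return np.mean(vals) if vals else np.nan


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return fn.BinaryGraph(tuple(range(1, n + 1)), a, 0.0)


class TestClosedForms:
    def test_triangle_all_ones(self):
        k3 = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        np.testing.assert_allclose(fn.nodal_clustering(k3), 1.0)
        np.testing.assert_allclose(fn.nodal_local_efficiency(k3), 1.0)

    def test_star_center_zero_clustering(self):
        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        ncp = fn.nodal_clustering(star)
        assert ncp[0] == 0.0
        np.testing.assert_allclose(ncp[1:], 0.0)  # leaves have degree 1

    def test_path3_metrics(self):
        p3 = graph_from_edges(3, [(0, 1), (1, 2)])
        assert fn.characteristic_path_length(p3) == pytest.approx(4.0 / 3.0)
        assert fn.global_efficiency(p3) == pytest.approx(5.0 / 6.0)
        nle = fn.nodal_local_efficiency(p3)
        assert nle[1] == 0.0  # middle node's neighbors are unconnected

    def test_complete_graph_metrics(self):
        for n in (4, 6):
            kn = graph_from_edges(n, itertools.combinations(range(n), 2))
            assert fn.characteristic_path_length(kn) == pytest.approx(1.0)
            assert fn.global_efficiency(kn) == pytest.approx(1.0)
            np.testing.assert_allclose(fn.nodal_clustering(kn), 1.0)

    def test_two_disconnected_dumbbells(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        assert fn.global_efficiency(g) == pytest.approx(1.0 / 3.0)
        # reachable-pairs convention: both reachable pairs at distance 1
        assert fn.characteristic_path_length(g) == pytest.approx(1.0)

    def test_edgeless_graph_lp_undefined(self):
        g = graph_from_edges(3, [])
        assert np.isnan(fn.characteristic_path_length(g))


class TestOracleEquivalence:
    def test_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(110):
            n = int(rng.integers(4, 16))
            g = random_binary_graph(rng, n, float(rng.uniform(0.1, 0.7)))
            adj = g.adjacency
            np.testing.assert_allclose(fn.nodal_clustering(g), brute_ncp(adj),
                                       atol=1e-12)
            np.testing.assert_allclose(fn.nodal_local_efficiency(g),
                                       brute_nle(adj), atol=1e-12)
            np.testing.assert_allclose(fn.global_efficiency(g), brute_eg(adj),
                                       atol=1e-12)
            lp = fn.characteristic_path_length(g)
            ref = brute_lp(adj)
            if np.isnan(ref):
                assert np.isnan(lp)
            else:
                assert lp == pytest.approx(ref, abs=1e-12)

    def test_against_networkx(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            g = random_binary_graph(rng, 12, 0.35)
            gx = nx.from_numpy_array(g.adjacency.astype(int))
            ncp = fn.nodal_clustering(g)
            nx_c = nx.clustering(gx)
            np.testing.assert_allclose(ncp, [nx_c[i] for i in range(12)],
                                       atol=1e-12)
            assert fn.global_efficiency(g) == pytest.approx(
                nx.global_efficiency(gx), abs=1e-12)

    def test_global_means_consistent_with_nodal(self):
        rng = np.random.default_rng(14)
        g = random_binary_graph(rng, 20, 0.3)
        m = nodal_metrics(g)
        gm = fn.compute_global_metrics(g, compute_sigma=False)
        assert gm.cp == pytest.approx(m.ncp.mean())
        assert gm.eloc == pytest.approx(m.nle.mean())

    def test_denser_graph_shorter_paths_higher_efficiency(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            g = random_binary_graph(rng, 15, 0.3)
            extra = g.adjacency.copy()
            i, j = rng.integers(0, 15, 2)
            while i == j or extra[i, j]:
                i, j = rng.integers(0, 15, 2)
            extra[i, j] = extra[j, i] = True
            g2 = fn.BinaryGraph(g.nodes, extra, 0.0)
            assert fn.global_efficiency(g2) >= fn.global_efficiency(g) - 1e-12


class TestNullEnsemble:
    def test_degree_sequence_preserved_and_seeded(self):
        rng = np.random.default_rng(16)
        g = random_binary_graph(rng, 30, 0.2)
        nulls = fn.random_null_ensemble(g, n_nulls=20, seed=42)
        for null in nulls:
            np.testing.assert_array_equal(null.degrees(), g.degrees())
        again = fn.random_null_ensemble(g, n_nulls=20, seed=42)
        for a, b in zip(nulls, again):
            np.testing.assert_array_equal(a.adjacency, b.adjacency)

    def test_rewiring_actually_changes_edges(self):
        rng = np.random.default_rng(17)
        g = random_binary_graph(rng, 30, 0.2)
        nulls = fn.random_null_ensemble(g, n_nulls=5, seed=0)
        assert any(not np.array_equal(n.adjacency, g.adjacency)
                   for n in nulls)

    def test_star_returns_copies_with_warning(self):
        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        with pytest.warns(UserWarning, match="rewired"):
            nulls = fn.random_null_ensemble(star, n_nulls=3, seed=0)
        for n in nulls:
            np.testing.assert_array_equal(n.adjacency, star.adjacency)

    def test_rewiring_destroys_lattice_clustering(self):
        gx = nx.watts_strogatz_graph(40, 6, 0.0, seed=1)
        adj = nx.to_numpy_array(gx).astype(bool)
        ring = fn.BinaryGraph(tuple(range(1, 41)), adj, 0.0)
        nulls = fn.random_null_ensemble(ring, n_nulls=20, seed=1)
        cp_ring = fn.nodal_clustering(ring).mean()
        cp_null = np.mean([fn.nodal_clustering(n).mean() for n in nulls])
        assert cp_null < cp_ring


class TestSmallWorldness:
    def test_self_null_gives_sigma_one(self):
        rng = np.random.default_rng(18)
        g = random_binary_graph(rng, 12, 0.4)
        sigma, _, _ = fn.small_worldness(g, [g])
        assert sigma == pytest.approx(1.0)

    def test_watts_strogatz_ring_is_small_world(self):
        gx = nx.watts_strogatz_graph(50, 6, 0.1, seed=3)
        g = fn.BinaryGraph(tuple(range(1, 51)),
                           nx.to_numpy_array(gx).astype(bool), 0.0)
        nulls = fn.random_null_ensemble(g, n_nulls=100, seed=3)
        sigma, _, _ = fn.small_worldness(g, nulls)
        assert sigma > 1.0

    def test_erdos_renyi_sigma_near_one(self):
        # a single realization's clustering fluctuates around the ensemble
        # value, so sigma ~ 1 holds on average over realizations
        sigmas = []
        for seed in range(6):
            gx = nx.gnp_random_graph(50, 0.2, seed=seed)
            g = fn.BinaryGraph(tuple(range(1, 51)),
                               nx.to_numpy_array(gx).astype(bool), 0.0)
            nulls = fn.random_null_ensemble(g, n_nulls=100, seed=seed)
            sigmas.append(fn.small_worldness(g, nulls)[0])
        assert np.mean(sigmas) == pytest.approx(1.0, abs=0.1)


class TestCurvesAndAuc:
    def test_constant_and_linear_curve_areas(self):
        taus = np.asarray(fn.DEFAULT_THRESHOLDS)
        assert trapezoid_auc(np.full(11, 0.5), taus) == pytest.approx(0.25)
        linear = np.linspace(1.0, 0.0, 11)
        assert trapezoid_auc(linear, taus) == pytest.approx(0.25)

    def test_sweep_reproducible(self, atlas, small_cohort):
        res = fn.run_preprocess(small_cohort.raws[0])
        cm = fn.build_connectivity(res.hemo.hbo, atlas)
        a = fn.metric_curves_and_auc(cm, n_nulls=10, seed=9)
        b = fn.metric_curves_and_auc(cm, n_nulls=10, seed=9)
        for name in a:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_curve_shapes(self, atlas, small_cohort):
        res = fn.run_preprocess(small_cohort.raws[0])
        cm = fn.build_connectivity(res.hemo.hbo, atlas)
        curves = fn.metric_curves_and_auc(cm, compute_sigma=False)
        assert curves["Cp"].values.shape == (11,)
        assert curves["NCp"].values.shape == (50, 11)
        assert curves["NCp"].auc.shape == (50,)


class TestRoiAverage:
    def test_uniform_values(self, atlas):
        nodes = atlas.lateral_channels
        vals = np.full(50, 0.7)
        out = fn.roi_average(vals, nodes, atlas)
        assert len(out) == 10
        assert all(v == pytest.approx(0.7) for v in out.values())

    def test_simple_mean_and_permutation_invariance(self, atlas):
        nodes = atlas.lateral_channels
        rng = np.random.default_rng(19)
        vals = rng.random(50)
        out = fn.roi_average(vals, nodes, atlas)
        (hemi, roi), members = next(iter(atlas.roi_groups().items()))
        idx = [nodes.index(c) for c in members]
        assert out[(hemi, roi)] == pytest.approx(vals[idx].mean())
        # permuting channels within the ROI leaves its mean unchanged
        vals2 = vals.copy()
        vals2[idx] = vals[idx[::-1]]
        assert fn.roi_average(vals2, nodes, atlas)[(hemi, roi)] == \
            pytest.approx(out[(hemi, roi)])
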