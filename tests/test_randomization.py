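"""Randomization tests, duration threshold, and cluster-extent calibration."""

import networkx as nx
import numpy as np
import pytest

from elneuro.preprocess import Erp
from elneuro.randomization import (
    GroupDesign,
    _observed_and_perm_stats,
    cluster_extent_threshold,
    duration_threshold,
    longest_run,
    perm_p_matrix,
    tf_randomization_test,
)
from elneuro.simulate import ErpSimConfig, simulate_erp_dataset

N_TF = 60


def _design_from_array(x: np.ndarray, n_a: int) -> GroupDesign:
    """x: subjects x sessions x channels x timeframes."""
    subjects = [f"s{i}" for i in range(x.shape[0])]
    group_of = {s: ("A" if i < n_a else "B") for i, s in enumerate(subjects)}
    erp_of = {}
    for i, s in enumerate(subjects):
        for j, sess in enumerate(("pre", "post")):
            erp_of[(s, sess)] = Erp(
                x[i, j] - x[i, j].mean(axis=0, keepdims=True),
                256.0, (-100.0, 700.0), sess, s, group_of[s],
                avg_referenced=True,
            )
    return GroupDesign(subjects, group_of, erp_of)


@pytest.fixture()
def random_design(rng):
    return _design_from_array(rng.standard_normal((12, 2, 8, N_TF)), 6)


class TestTfRandomizationTest:
    def test_identical_cells_give_p_one(self):
        # every subject identical in every cell: the statistic is invariant
        # under any relabeling, so all p-values are 1 by the tie convention
        one = np.random.default_rng(0).standard_normal((8, N_TF))
        x = np.broadcast_to(one, (10, 2, 8, N_TF)).copy()
        d = _design_from_array(x, 5)
        for metric in ("gfp", "topo"):
            for effect in ("session", "group", "interaction"):
                res = tf_randomization_test(d, metric, effect, n_perm=200, seed=1)
                np.testing.assert_array_equal(res.p, 1.0)

    def test_p_value_convention_never_zero(self, random_design):
        res = tf_randomization_test(random_design, "gfp", "session", n_perm=200, seed=2)
        assert res.p.min() >= 1.0 / 201.0
        assert res.p.max() <= 1.0

    def test_pointwise_type_i_error_calibrated(self):
        # null data: pointwise rejection fraction at alpha=.05 pooled over
        # timeframes and replicate datasets stays near .05
        rejs = []
        for i in range(40):
            g = np.random.default_rng(100 + i)
            d = _design_from_array(g.standard_normal((12, 2, 8, N_TF)), 6)
            res = tf_randomization_test(d, "topo", "interaction", n_perm=300, seed=i)
            rejs.append((res.p < 0.05).mean())
        assert np.mean(rejs) == pytest.approx(0.05, abs=0.012)

    def test_gfp_and_topo_statistics_orthogonal(self, rng):
        # rescaling one cell's maps moves the gfp statistic but leaves the
        # topographic statistic exactly unchanged
        x = rng.standard_normal((12, 2, 8, N_TF))
        d1 = _design_from_array(x, 6)
        x2 = x.copy()
        x2[:6, 1] *= 3.0  # scale group A post maps
        d2 = _design_from_array(x2, 6)
        for metric, should_change in [("gfp", True), ("topo", False)]:
            r1 = tf_randomization_test(d1, metric, "interaction", n_perm=100, seed=3)
            r2 = tf_randomization_test(d2, metric, "interaction", n_perm=100, seed=3)
            if should_change:
                assert not np.allclose(r1.stat, r2.stat)
            else:
                np.testing.assert_allclose(r1.stat, r2.stat, atol=1e-12)

    def test_same_seed_reproducible(self, random_design):
        r1 = tf_randomization_test(random_design, "topo", "group", n_perm=200, seed=9)
        r2 = tf_randomization_test(random_design, "topo", "group", n_perm=200, seed=9)
        np.testing.assert_array_equal(r1.p, r2.p)
        assert r1.duration_threshold_tf == r2.duration_threshold_tf

    def test_unknown_metric_effect_rejected(self, random_design):
        with pytest.raises(ValueError):
            tf_randomization_test(random_design, "power", "session")
        with pytest.raises(ValueError):
            tf_randomization_test(random_design, "gfp", "main")


class TestPermPMatrix:
    def test_columns_uniform_on_rank_grid(self, random_design, rng):
        from elneuro.randomization import _pseudo_p

        m = perm_p_matrix(random_design, "gfp", "session", n_perm=100, seed=4)
        assert m.shape == (100, N_TF)
        assert m.min() > 0 and m.max() <= 1.0
        # columns are rank-uniform: every column mean is (P+1)/2P exactly
        np.testing.assert_allclose(m.mean(axis=0), 101 / 200.0, atol=1e-12)
        # with distinct values each column is exactly the grid {1/P, ..., 1}
        distinct = _pseudo_p(rng.standard_normal((100, 5)))
        for col in distinct.T:
            np.testing.assert_allclose(np.sort(col), np.arange(1, 101) / 100.0)

    def test_seed_determinism(self, random_design):
        a = perm_p_matrix(random_design, "topo", "interaction", n_perm=100, seed=5)
        b = perm_p_matrix(random_design, "topo", "interaction", n_perm=100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_consistent_with_observed_p(self, random_design):
        # the pointwise p of the test equals the right-tail count of the
        # observed statistic in the same permutation pool
        obs, perm = _observed_and_perm_stats(random_design, "gfp", "session", 200, 6)
        p_manual = np.array(
            [(1 + (perm[:, t] >= obs[t]).sum()) / 201.0 for t in range(N_TF)]
        )
        res = tf_randomization_test(random_design, "gfp", "session", n_perm=200, seed=6)
        np.testing.assert_allclose(res.p, p_manual, atol=1e-12)


def _oracle_duration_threshold(sig: np.ndarray, alpha: float) -> int:
    """Brute-force longest-run threshold: scan run lengths directly."""
    runs = []
    for row in sig:
        best = cur = 0
        for v in row:
            cur = cur + 1 if v else 0
            best = max(best, cur)
        runs.append(best)
    runs = np.array(runs)
    for ell in range(1, sig.shape[1] + 2):
        if (runs >= ell).mean() <= alpha:
            return ell
    raise AssertionError


class TestDurationThreshold:
    def test_all_null_series_give_one(self):
        assert duration_threshold(np.full((500, 50), 0.5), 0.05) == 1

    def test_matches_bernoulli_longest_run_oracle(self):
        # iid Bernoulli(.05) significance over T=200, 10,000 draws
        g = np.random.default_rng(17)
        p = g.random((10_000, 200))
        ours = duration_threshold(p, alpha=0.05)
        oracle = _oracle_duration_threshold(p < 0.05, 0.05)
        assert ours == oracle

    def test_monotone_in_alpha(self):
        g = np.random.default_rng(3)
        p = g.random((2000, 100))
        l_prev = None
        for alpha in (0.10, 0.05, 0.01):
            l_now = duration_threshold(p, alpha)
            if l_prev is not None:
                assert l_now <= l_prev
            l_prev = l_now

    def test_longest_run_helper(self):
        assert longest_run(np.array([0, 1, 1, 1, 0, 1], dtype=bool)) == 3
        assert longest_run(np.zeros(5, dtype=bool)) == 0


def _oracle_chain_ke(n_nodes, alpha_node, fwer, n_mc, seed):
    """Independent chain-graph oracle: supra-threshold clusters on a chain
    are runs, so the max cluster is the longest run of |z| > z_crit."""
    from scipy.stats import norm

    g = np.random.default_rng(seed)
    z_crit = norm.ppf(1 - alpha_node / 2)
    maxes = longest_run(np.abs(g.standard_normal((n_mc, n_nodes))) > z_crit)
    for ke in range(1, n_nodes + 2):
        if (maxes >= ke).mean() <= fwer:
            return ke
    raise AssertionError


class TestClusterExtent:
    def test_chain_matches_run_length_oracle(self):
        chain = nx.path_graph(100)
        ke = cluster_extent_threshold(chain, 0.0, 0.05, 0.05, n_mc=10_000, seed=0)
        oracle = _oracle_chain_ke(100, 0.05, 0.05, 10_000, seed=999)
        assert ke == oracle

    def test_monotone_in_smoothing(self):
        chain = nx.path_graph(60)
        kes = [
            cluster_extent_threshold(chain, f, 0.05, 0.05, n_mc=2000, seed=1)
            for f in (0.0, 2.0, 4.0)
        ]
        assert kes[0] <= kes[1] <= kes[2]

    def test_fwer_one_gives_one(self):
        assert cluster_extent_threshold(nx.path_graph(20), 0.0, 0.05, 1.0,
                                        n_mc=1000, seed=2) == 1

    def test_disconnected_graph_rejected(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            cluster_extent_threshold(g, 0.0, n_mc=1000)


class TestEffectRecoveryOnSimulatedData:
    def test_gain_injection_found_by_gfp_not_topo(self):
        from elneuro.simulate import EffectSpec

        cfg = ErpSimConfig(
            n_per_group=16, snr=5.0, seed=21,
            effects=(
                EffectSpec(kind="gain", window_ms=(350.0, 500.0), group="A",
                           session="post", gain=1.3),
            ),
        )
        d = simulate_erp_dataset(cfg)
        t = d.erp_of[(d.subjects[0], "pre")].times_ms()
        rg = tf_randomization_test(d, "gfp", "interaction", n_perm=400, seed=22)
        rt = tf_randomization_test(d, "topo", "interaction", n_perm=400, seed=22)
        assert any(t[a] < 500.0 and t[b] > 350.0 for a, b in rg.pois)
        assert rt.pois == []
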