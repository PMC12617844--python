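"""Connectivity matrices, FDR, omnibus inference, permutation tests."""

import numpy as np
import pytest

from breathlock import (
    ConnectivityStack,
    SimConfig,
    bh_fdr,
    fisher_z,
    gen_cohort_connectivity,
    paired_connection_tests,
    paired_permutation_test,
    regress_confounds,
    roi_connectivity_matrix,
    roi_omnibus_inference,
)


def brute_force_bh(p):
    """Literal step-up definition, kept independent of the implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


class TestRegressConfounds:
    def test_orthogonal_confounds_leave_series_alone(self, rng):
        n = 200
        series = np.sin(2 * np.pi * 5 * np.arange(n) / n)[:, None]
        conf = np.cos(2 * np.pi * 7 * np.arange(n) / n)[:, None]
        out = regress_confounds(series, conf, add_linear_trend=False)
        assert np.allclose(out, series - series.mean(), atol=1e-10)

    def test_exact_trend_removed(self):
        series = np.linspace(0, 5, 100)[:, None]
        out = regress_confounds(series, None)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        series = rng.standard_normal((150, 4))
        conf = rng.standard_normal((150, 6))
        out = regress_confounds(series, conf)
        assert np.max(np.abs(conf.T @ out)) < 1e-8
        assert np.max(np.abs(out.sum(axis=0))) < 1e-8

    def test_collinear_design_named(self, rng):
        conf = rng.standard_normal((50, 2))
        conf = np.column_stack([conf, conf[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            regress_confounds(rng.standard_normal((50, 2)), conf)


class TestConnectivityMatrix:
    def test_fisher_z_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(1.5 / 0.5),
                                              abs=1e-12)

    def test_fisher_z_is_odd(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        assert np.allclose(fisher_z(-r), -np.asarray(fisher_z(r)))

    def test_duplicated_roi_clamped(self, rng):
        x = rng.standard_normal(100)
        data = np.column_stack([x, x, rng.standard_normal(100)])
        z = roi_connectivity_matrix(data)
        assert z[0, 1] > 13  # atanh(1 - 1e-12) ~ 14.2, finite
        assert np.isfinite(z[0, 1])

    def test_symmetric_nan_diagonal(self, rng):
        z = roi_connectivity_matrix(rng.standard_normal((300, 6)))
        assert np.isnan(np.diag(z)).all()
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(z[off], z.T[off], atol=1e-12)
        assert abs(np.nanmean(z[off])) < 0.05  # independent noise -> ~0

    def test_zero_variance_roi_flagged(self, rng):
        data = rng.standard_normal((50, 3))
        data[:, 1] = 2.0
        with pytest.warns(UserWarning):
            z = roi_connectivity_matrix(data)
        assert np.isnan(z[1, :]).all()


class TestBhFdr:
    def test_hand_step_up_example(self):
        out = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for m in (7, 50, 200):
            p = rng.uniform(0, 1, m)
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))


class TestPairedPermutation:
    def test_identical_samples_give_p_one(self):
        a = np.arange(8.0)
        assert paired_permutation_test(a, a.copy()) == pytest.approx(1.0)

    def test_exact_enumeration_n3(self):
        # full 2^3 enumeration: all diffs +1 -> two-sided p = 2/8
        p = paired_permutation_test(np.ones(3), np.zeros(3))
        assert p == pytest.approx(0.25)

    def test_exact_matches_sign_test_on_unit_diffs(self):
        from scipy.stats import binom
        for n in (5, 8, 10):
            p = paired_permutation_test(np.ones(n), np.zeros(n))
            # closed-form two-sided sign-test p on +/-1 differences
            expected = 2 * binom.cdf(0, n, 0.5)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_close_to_exact(self, rng):
        a = rng.standard_normal(18)
        b = a + 0.6 + 0.3 * rng.standard_normal(18)
        p_mc = paired_permutation_test(a, b, n_iter=40_000, seed=1)
        p_ex = paired_permutation_test(a, b, n_iter=2**18, seed=1)
        assert p_mc == pytest.approx(p_ex, abs=0.01)


class TestConnectionTests:
    @pytest.fixture(scope="class")
    def stacks(self):
        cfg = SimConfig(n_subjects=20, n_rois=30, effect_z=0.3, seed=5)
        a, b, _ = gen_cohort_connectivity(cfg)
        return a, b, cfg

    def test_identical_stacks_select_nothing(self, stacks):
        a, _, _ = stacks
        same = ConnectivityStack(a.data.copy(), a.roi_labels, "B")
        out = paired_connection_tests(a, same, 0)
        assert np.allclose(out["t"], 0.0)
        assert not out["selected"].any()

    def test_hub_connections_recovered(self, stacks):
        a, b, cfg = stacks
        out = paired_connection_tests(a, b, cfg.hub_a)
        # condition A boosts hub_a: the selected connections point A>B
        sel = out[out["selected"]]
        assert len(sel) >= 0.8 * (cfg.n_rois - 1)
        assert (sel["direction"] == "A>B").all()

    def test_needs_three_subjects(self, stacks):
        a, b, _ = stacks
        small_a = ConnectivityStack(a.data[:2], a.roi_labels, "A")
        small_b = ConnectivityStack(b.data[:2], b.roi_labels, "B")
        with pytest.raises(ValueError):
            paired_connection_tests(small_a, small_b, 0)


class TestOmnibus:
    def test_identical_stacks_nothing_significant(self):
        cfg = SimConfig(n_subjects=10, n_rois=15, seed=3)
        a, _, _ = gen_cohort_connectivity(cfg)
        same = ConnectivityStack(a.data.copy(), a.roi_labels, "B")
        res = roi_omnibus_inference(a, same)
        assert res.significant_rois == []

    def test_recovers_planted_hubs(self):
        cfg = SimConfig(n_subjects=20, n_rois=40, effect_z=0.3, seed=8)
        a, b, truth = gen_cohort_connectivity(cfg)
        res = roi_omnibus_inference(a, b)
        sig = set(res.significant_rois)
        assert {a.roi_labels[truth["hub_a"]],
                a.roi_labels[truth["hub_b"]]} <= sig

    def test_f_dof_follow_k(self):
        cfg = SimConfig(n_subjects=20, n_rois=12, seed=9)
        a, b, _ = gen_cohort_connectivity(cfg)
        res = roi_omnibus_inference(a, b, k=2)
        assert (res.table["df1"] == 2).all()
        assert (res.table["df2"] == 18).all()
        assert (res.table["F"] >= 0).all()

    def test_needs_enough_subjects(self):
        cfg = SimConfig(n_subjects=2, n_rois=8, seed=1)
        a, b, _ = gen_cohort_connectivity(cfg)
        with pytest.raises(ValueError):
            roi_omnibus_inference(a, b, k=2)
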