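"""Physiological metric extraction, response-function regressors, outliers."""

import numpy as np
import pytest

from breathlock import (
    CardiacSeries,
    RespirationTrace,
    bold_physio_coupling,
    compute_rvt,
    crf_kernel,
    detect_breath_extrema,
    heart_rate,
    iqr_outlier_flags,
    physio_regressor,
    respiration_frequency,
    rmssd,
    rrf_kernel,
)


def sinusoid(f, duration, fs, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return RespirationTrace(samples=np.sin(2 * np.pi * f * t + phase), fs=fs)


class TestBreathExtrema:
    def test_sinusoid_peak_count(self):
        # 0.3 Hz over 60 s: peaks at t = (k + 1/4)/0.3 < 60 -> 18 peaks
        peaks, troughs = detect_breath_extrema(sinusoid(0.3, 60, 50))
        assert peaks.size == 18
        assert abs(troughs.size - peaks.size) <= 1

    def test_alternation_of_extrema(self):
        peaks, troughs = detect_breath_extrema(sinusoid(0.25, 80, 40))
        merged = np.sort(np.concatenate([peaks, troughs]))
        kinds = np.isin(merged, peaks).astype(int)
        assert np.all(np.abs(np.diff(kinds)) == 1)

    def test_noise_robustness(self, rng):
        # oracle: the noiseless detection count
        clean = sinusoid(0.3, 60, 50)
        peaks_clean, _ = detect_breath_extrema(clean)
        noisy = RespirationTrace(
            samples=clean.samples + 0.01 * rng.standard_normal(3000), fs=50)
        peaks_noisy, _ = detect_breath_extrema(noisy)
        assert peaks_noisy.size == peaks_clean.size

    def test_constant_trace_raises(self):
        with pytest.raises(ValueError):
            detect_breath_extrema(RespirationTrace(np.ones(1000), fs=50))


class TestRespirationFrequency:
    def test_pure_tone(self):
        assert respiration_frequency(sinusoid(0.31, 300, 50)) == \
            pytest.approx(0.31, rel=1e-3)

    def test_two_segment_signal_matches_enumeration_oracle(self):
        # 0.25 Hz for 30 s then 0.35 Hz for 30 s with continuous phase.
        fs = 50.0
        t = np.arange(int(60 * fs)) / fs
        f_inst = np.where(t < 30, 0.25, 0.35)
        phase = 2 * np.pi * np.cumsum(f_inst) / fs
        trace = RespirationTrace(np.sin(phase), fs=fs)
        # oracle: peaks sit where phase crosses pi/2 + 2*pi*k; enumerate them
        targets = np.pi / 2 + 2 * np.pi * np.arange(0, 60)
        crossing_t = np.interp(targets, phase, t, right=np.nan)
        crossing_t = crossing_t[np.isfinite(crossing_t)]
        crossing_t = crossing_t[crossing_t < t[-1] - 1e-6]
        expected = (crossing_t.size - 1) / (crossing_t[-1] - crossing_t[0])
        assert respiration_frequency(trace) == pytest.approx(expected, rel=0.02)

    def test_agrees_with_spectral_peak_on_clean_signal(self):
        from scipy.signal import welch
        trace = sinusoid(0.27, 300, 50)
        f, p = welch(trace.samples, fs=50, nperseg=4096)
        spectral = f[np.argmax(p)]
        assert respiration_frequency(trace) == pytest.approx(spectral, rel=0.1)


class TestHeartMetrics:
    def test_constant_rr(self):
        c = CardiacSeries(rr_ms=np.array([1000.0, 1000.0, 1000.0]))
        assert heart_rate(c) == pytest.approx(60.0)
        assert rmssd(c) == pytest.approx(0.0)

    def test_rmssd_hand_arithmetic(self):
        # diffs 50, -50 -> sqrt((50^2 + 50^2)/2) = 50
        c = CardiacSeries(rr_ms=np.array([800.0, 850.0, 800.0]))
        assert rmssd(c) == pytest.approx(50.0)

    def test_rmssd_shift_invariance(self):
        c1 = CardiacSeries(rr_ms=np.array([800.0, 900.0, 850.0, 870.0]))
        c2 = CardiacSeries(rr_ms=c1.rr_ms + 200.0)
        assert rmssd(c1) == pytest.approx(rmssd(c2))

    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            heart_rate(CardiacSeries(rr_ms=np.array([900.0])))
        with pytest.raises(ValueError):
            rmssd(CardiacSeries(rr_ms=np.array([900.0, 950.0])))


class TestRvt:
    def test_unit_sinusoid_analytic_value(self):
        # peak-to-trough 2 over half a 4 s period -> RVT = 1.0 per s
        _, rvt = compute_rvt(sinusoid(0.25, 120, 50))
        mid = rvt[1000:-1000]
        assert np.allclose(mid, 1.0, atol=0.02)

    def test_amplitude_homogeneity(self):
        tr = sinusoid(0.25, 120, 50)
        doubled = RespirationTrace(2 * tr.samples, fs=50)
        _, r1 = compute_rvt(tr)
        _, r2 = compute_rvt(doubled)
        assert np.allclose(r2, 2 * r1, rtol=1e-6)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            compute_rvt(RespirationTrace(np.zeros(5000), fs=50))


class TestResponseFunctions:
    def test_rrf_zero_at_origin(self):
        assert rrf_kernel(np.array([0.0]))[0] == 0.0

    def test_rrf_undershoot_lobe(self):
        # direct evaluation: the late lobe is negative
        assert rrf_kernel(np.array([20.0]))[0] < 0

    def test_crf_late_undershoot(self):
        assert crf_kernel(np.array([12.0]))[0] < 0

    def test_impulse_reproduces_sampled_kernel(self):
        fs, tr = 10.0, 0.5
        x = np.zeros(1200)
        x[0] = 1.0
        reg = physio_regressor(x, fs, "RRF", tr)
        tk = np.arange(reg.values.size) * tr
        expect = rrf_kernel(tk)
        # the regressor demeans its input; correct for the -1/n offset
        step = rrf_kernel(np.arange(0.0, 60.0, 1 / fs))
        assert np.allclose(reg.values[:100], expect[:100], atol=1.5 *
                           np.abs(step).sum() / x.size)

    def test_linearity_in_input_scale(self, rng):
        x = rng.standard_normal(600)
        r1 = physio_regressor(x, 10.0, "CRF", 2.0)
        r2 = physio_regressor(3 * x, 10.0, "CRF", 2.0)
        assert np.allclose(r2.values, 3 * r1.values, atol=1e-10)


class TestIqrRule:
    def test_single_outlier_flagged(self):
        d = np.array([0.01] * 19 + [0.5])
        flags = iqr_outlier_flags(d)
        assert flags.sum() == 1 and flags[-1]

    def test_all_equal_none_flagged(self):
        assert not iqr_outlier_flags(np.full(10, 0.3)).any()

    def test_mild_symmetric_spread_unflagged(self):
        # brute-force check against the quartile arithmetic
        d = np.array([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0])
        q1, q3 = np.percentile(d, [25, 75])
        iqr = q3 - q1
        expected = (d < q1 - 2 * iqr) | (d > q3 + 2 * iqr)
        assert not expected.any()
        assert np.array_equal(iqr_outlier_flags(d), expected)


class TestBoldPhysioCoupling:
    def test_identical_conditions_give_t_zero_p_one(self, rng):
        bold = rng.standard_normal((5, 100, 4))
        reg = rng.standard_normal((5, 100))
        out = bold_physio_coupling(bold, bold.copy(), reg, reg.copy())
        assert np.allclose(out["t_paired"], 0.0)
        assert np.allclose(out["p_unc"], 1.0)

    def test_regressor_equal_to_roi_gives_unit_r(self, rng):
        reg = rng.standard_normal((4, 80))
        bold = rng.standard_normal((4, 80, 3))
        bold[:, :, 1] = reg
        out = bold_physio_coupling(bold, rng.standard_normal((4, 80, 3)),
                                   reg, rng.standard_normal((4, 80)))
        assert out.loc[1, "r_A"] == pytest.approx(1.0)
        assert np.isfinite(out.loc[1, "z_A"])  # clamped, not inf

    def test_null_calibration_small(self, rng):
        # independent regressors: false-positive ROIs at FDR 0.05 are rare
        hits = 0
        for _ in range(20):
            bold_a = rng.standard_normal((10, 120, 8))
            bold_b = rng.standard_normal((10, 120, 8))
            reg_a = rng.standard_normal((10, 120))
            reg_b = rng.standard_normal((10, 120))
            out = bold_physio_coupling(bold_a, bold_b, reg_a, reg_b)
            hits += int((out["p_fdr"] < 0.05).sum() > 0)
        assert hits <= 3
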