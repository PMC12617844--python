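"""Instantaneous-frequency surrogates, thresholds, and %sigbins."""

import numpy as np
import pytest

from breathlock import (
    PhaseSeries,
    PlvSeries,
    iaaft,
    instantaneous_phase,
    percent_sigbins,
    plv_significance_threshold,
    respiration_bold_sigbins,
    s4_surrogates,
)


def phase_of_tone(f=0.16, duration=2400, fs=0.5):
    x = np.sin(2 * np.pi * f * np.arange(int(duration * fs)) / fs)
    return instantaneous_phase(x, fs)


class TestIaaft:
    def test_preserves_value_multiset(self, rng):
        x = rng.standard_normal(256)
        y = iaaft(x, rng)
        assert np.allclose(np.sort(x), np.sort(y))

    def test_preserves_power_spectrum(self, rng):
        # spectral oracle: periodogram correlation across draws
        t = np.arange(512)
        x = np.sin(0.2 * t) + 0.5 * np.sin(0.5 * t) + \
            0.3 * rng.standard_normal(512)
        px = np.abs(np.fft.rfft(x))**2
        corrs = []
        for _ in range(20):
            y = iaaft(x, rng)
            py = np.abs(np.fft.rfft(y))**2
            corrs.append(np.corrcoef(px[1:], py[1:])[0, 1])
        assert np.mean(corrs) > 0.95

    def test_constant_input_passthrough(self, rng):
        x = np.full(64, 2.5)
        assert np.array_equal(iaaft(x, rng), x)


class TestS4Surrogates:
    def test_pure_tone_surrogates_identical(self):
        # constant IF: nothing to permute
        ph = phase_of_tone()
        surr = s4_surrogates(ph, n=5, method="permute", seed=0)
        for s in surr:
            d = np.angle(np.exp(1j * (s.phi - ph.phi)))
            assert np.max(np.abs(d[ph.valid])) < 0.05

    def test_permute_preserves_if_multiset(self, coupled_pair):
        resp, _ = coupled_pair
        from breathlock import bandpass_filter, resample_trace
        x = resample_trace(bandpass_filter(resp.samples, 50, 0.01, 0.25),
                           50, 0.5)
        ph = instantaneous_phase(x, 0.5)
        surr = s4_surrogates(ph, n=3, method="permute", seed=1)
        inc = np.diff(ph.unwrapped)
        for s in surr:
            assert np.allclose(np.sort(np.diff(s.unwrapped)), np.sort(inc),
                               atol=1e-9)

    def test_iaaft_preserves_if_spectrum(self, coupled_pair):
        resp, _ = coupled_pair
        from breathlock import bandpass_filter, resample_trace
        x = resample_trace(bandpass_filter(resp.samples, 50, 0.01, 0.25),
                           50, 0.5)
        ph = instantaneous_phase(x, 0.5)
        valid_idx = np.flatnonzero(ph.valid)
        i0, i1 = valid_idx[0], valid_idx[-1]
        inc = np.diff(ph.unwrapped)[i0:i1]  # the resampled interior
        p_orig = np.abs(np.fft.rfft(inc))**2
        surr = s4_surrogates(ph, n=10, method="iaaft", seed=2)
        corrs = []
        for s in surr:
            p_s = np.abs(np.fft.rfft(np.diff(s.unwrapped)[i0:i1]))**2
            corrs.append(np.corrcoef(p_orig[1:], p_s[1:])[0, 1])
        assert np.mean(corrs) > 0.95

    def test_seed_determinism(self):
        ph = phase_of_tone()
        a = s4_surrogates(ph, n=3, method="iaaft", seed=5)
        b = s4_surrogates(ph, n=3, method="iaaft", seed=5)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.phi, sb.phi)

    def test_rejects_bad_args(self):
        ph = phase_of_tone()
        with pytest.raises(ValueError):
            s4_surrogates(ph, n=0)
        with pytest.raises(ValueError):
            s4_surrogates(ph, n=2, method="bogus")


class TestThreshold:
    def test_degenerate_null(self):
        null = np.full((50, 20), 0.3)
        assert plv_significance_threshold(null) == pytest.approx(0.3)

    def test_uniform_null_order_statistic(self, rng):
        null = rng.uniform(0, 1, (1000, 200))
        thr = plv_significance_threshold(null, alpha=0.05, mode="global")
        assert thr == pytest.approx(0.95, abs=0.005)

    def test_alpha_half_gives_median(self, rng):
        null = rng.uniform(0, 1, (2000, 50))
        thr = plv_significance_threshold(null, alpha=0.5, mode="global")
        assert thr == pytest.approx(np.median(null), abs=0.01)

    def test_per_bin_mode_shape(self, rng):
        null = rng.uniform(0, 1, (200, 30))
        null[:, 0] = np.nan
        thr = plv_significance_threshold(null, mode="per_bin")
        assert thr.shape == (30,)
        assert np.isnan(thr[0]) and np.isfinite(thr[1:]).all()

    def test_all_invalid_raises(self):
        with pytest.raises(ValueError):
            plv_significance_threshold(np.full((10, 5), np.nan))


class TestPercentSigbins:
    def make_plv(self, values):
        n = len(values)
        return PlvSeries(values=np.asarray(values, dtype=float),
                         window_samples=13, times=np.arange(n) * 2.0,
                         valid=np.ones(n, dtype=bool))

    def test_all_below_threshold(self):
        res = percent_sigbins(self.make_plv([0.1] * 50), 0.5)
        assert res.percent_sigbins == 0.0
        assert not res.reliable

    def test_exactly_ten_percent_is_reliable(self):
        vals = [0.9] * 10 + [0.1] * 90
        res = percent_sigbins(self.make_plv(vals), 0.5)
        assert res.percent_sigbins == pytest.approx(10.0)
        assert res.reliable  # the rule is >= 10, not > 10

    def test_ties_at_threshold_not_significant(self):
        res = percent_sigbins(self.make_plv([0.5] * 20), 0.5)
        assert res.percent_sigbins == 0.0

    def test_no_valid_bins_raises(self):
        plv = self.make_plv([0.5] * 10)
        plv.valid[:] = False
        with pytest.raises(ValueError):
            percent_sigbins(plv, 0.3)


class TestEndToEnd:
    def test_pipeline_deterministic(self, coupled_pair):
        resp, bold = coupled_pair
        a = respiration_bold_sigbins(resp, bold.data[:, 0], 2.0,
                                     n_surrogates=50, seed=11)
        b = respiration_bold_sigbins(resp, bold.data[:, 0], 2.0,
                                     n_surrogates=50, seed=11)
        assert a.percent_sigbins == b.percent_sigbins

    def test_coupled_roi_beats_uncoupled(self, coupled_pair):
        resp, bold = coupled_pair
        hit = respiration_bold_sigbins(resp, bold.data[:, 0], 2.0,
                                       n_surrogates=100, seed=3)
        miss = respiration_bold_sigbins(resp, bold.data[:, 1], 2.0,
                                        n_surrogates=100, seed=3)
        assert hit.percent_sigbins > miss.percent_sigbins
        assert hit.reliable
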