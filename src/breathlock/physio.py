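"""Physiological metrics, nuisance regressors, and the BOLD-physiology control.

Covers respiration-frequency and heart-rate extraction, RMSSD, respiratory
volume per time (RVT), heart-rate-variability (HRV) regressor construction by
convolution with the canonical respiration/cardiac response functions, the
2xIQR between-condition outlier rule, and the per-ROI BOLD-physiology
coupling comparison (Pearson r -> Fisher Z -> paired t -> BH-FDR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import ttest_rel

from .types import CardiacSeries, PhysioRegressor, PhysioSummary, RespirationTrace

__all__ = [
    "detect_breath_extrema",
    "respiration_frequency",
    "heart_rate",
    "rmssd",
    "compute_rvt",
    "hrv_series",
    "rrf_kernel",
    "crf_kernel",
    "physio_regressor",
    "iqr_outlier_flags",
    "bold_physio_coupling",
    "physio_summary",
]


def detect_breath_extrema(trace: RespirationTrace) -> tuple[np.ndarray, np.ndarray]:
    """Alternating inhalation peaks and exhalation troughs.

    Peaks/troughs are prominence-filtered at 0.25x a robust amplitude
    estimate (the 10th-90th percentile span) and then pruned so maxima and
    minima strictly alternate, keeping the most extreme sample within any
    same-type run. Raises on (near-)constant traces.
    """
    x = trace.samples
    amp = np.percentile(x, 90) - np.percentile(x, 10)
    if amp <= 0 or np.ptp(x) == 0:
        raise ValueError("no breath extrema detectable in a constant trace")
    prom = 0.25 * amp
    peaks, _ = find_peaks(x, prominence=prom)
    troughs, _ = find_peaks(-x, prominence=prom)
    if peaks.size == 0 or troughs.size == 0:
        raise ValueError("no breath extrema found")
    # enforce strict alternation: merge, sort, keep extremum of each run
    events = sorted([(i, +1) for i in peaks] + [(i, -1) for i in troughs])
    kept: list[tuple[int, int]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = x[idx] > x[prev] if kind > 0 else x[idx] < x[prev]
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    peaks = np.array([i for i, k in kept if k > 0])
    troughs = np.array([i for i, k in kept if k < 0])
    return peaks, troughs


def respiration_frequency(trace: RespirationTrace) -> float:
    """Mean breathing rate in Hz from the peak count.

    (number of peaks - 1) divided by the time between the first and last
    inhalation peak.
    """
    peaks, _ = detect_breath_extrema(trace)
    if peaks.size < 2:
        raise ValueError("fewer than two breaths detected")
    span = (peaks[-1] - peaks[0]) / trace.fs
    return (peaks.size - 1) / span


def heart_rate(cardiac: CardiacSeries) -> float:
    """Mean heart rate in beats/min: 60000 / mean RR (ms)."""
    if cardiac.rr_ms.size < 2:
        raise ValueError("need at least two RR intervals")
    return 60000.0 / float(np.mean(cardiac.rr_ms))


def rmssd(cardiac: CardiacSeries) -> float:
    """Root mean square of successive RR-interval differences (ms)."""
    if cardiac.rr_ms.size < 3:
        raise ValueError("need at least three RR intervals for RMSSD")
    d = np.diff(cardiac.rr_ms)
    return float(np.sqrt(np.mean(d * d)))


def physio_summary(resp: RespirationTrace, cardiac: CardiacSeries) -> PhysioSummary:
    return PhysioSummary(rf_hz=respiration_frequency(resp),
                         hr_bpm=heart_rate(cardiac),
                         rmssd_ms=rmssd(cardiac))


def compute_rvt(trace: RespirationTrace,
                grid_times: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Respiratory volume per time.

    At each inhalation peak: (peak amplitude - next trough amplitude)
    divided by the time from peak to trough (breath depth over breath
    duration), linearly interpolated onto ``grid_times`` (default: the
    trace's own sample grid). Returns ``(times, values)``.
    """
    peaks, troughs = detect_breath_extrema(trace)
    x, fs = trace.samples, trace.fs
    vals, times = [], []
    for p in peaks:
        later = troughs[troughs > p]
        if later.size == 0:
            break
        tr_i = later[0]
        depth = x[p] - x[tr_i]
        dur = (tr_i - p) / fs
        if dur > 0:
            vals.append(depth / dur)
            times.append(p / fs)
    if not vals:
        raise ValueError("no complete breaths for RVT")
    times = np.asarray(times)
    vals = np.asarray(vals)
    if grid_times is None:
        grid_times = trace.times
    return grid_times, np.interp(grid_times, times, vals)


def hrv_series(cardiac: CardiacSeries, fs: float,
               duration_s: float) -> tuple[np.ndarray, np.ndarray]:
    """RR-interval time course interpolated onto a uniform grid.

    The heart-rate-variability input to the cardiac response function: the
    RR sequence indexed at beat times, linearly interpolated (toolbox
    convention of using the interpolated RR series rather than instantaneous
    HR).
    """
    t = np.arange(int(round(duration_s * fs))) / fs
    beats = cardiac.beat_times_s
    return t, np.interp(t, beats, cardiac.rr_ms)


def rrf_kernel(t: np.ndarray) -> np.ndarray:
    """Respiration response function.

    RRF(t) = 0.6 t^2.1 exp(-t/1.6) - 0.0023 t^3.54 exp(-t/4.25),
    t in seconds: an early overshoot followed by a slow undershoot.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = (0.6 * tp**2.1 * np.exp(-tp / 1.6)
                - 0.0023 * tp**3.54 * np.exp(-tp / 4.25))
    return out


def crf_kernel(t: np.ndarray) -> np.ndarray:
    """Cardiac response function.

    CRF(t) = 0.6 t^2.7 exp(-t/1.6) - 16/sqrt(18*pi) exp(-(t-12)^2/18).
    """
    t = np.asarray(t, dtype=float)
    out = -16.0 / np.sqrt(18.0 * np.pi) * np.exp(-((t - 12.0) ** 2) / 18.0)
    pos = t > 0
    tp = t[pos]
    out[pos] += 0.6 * tp**2.7 * np.exp(-tp / 1.6)
    out[t < 0] = 0.0
    return out


_KERNELS = {"RRF": rrf_kernel, "CRF": crf_kernel}


def physio_regressor(values: np.ndarray, fs: float, kernel: str, tr: float,
                     kind: str | None = None,
                     truncate_s: float = 60.0) -> PhysioRegressor:
    """Convolve a physiological series with its response function.

    ``values`` must be uniformly sampled at ``fs``. The kernel (RRF or CRF)
    is sampled at ``fs`` and truncated at ``truncate_s``; the discrete
    convolution (an impulse maps to the sampled kernel) is then linearly
    resampled onto the TR grid.
    """
    values = np.asarray(values, dtype=float)
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")
    tk = np.arange(0.0, truncate_s, 1.0 / fs)
    k = _KERNELS[kernel](tk)
    conv = np.convolve(values - values.mean(), k)[: values.size]
    t_in = np.arange(values.size) / fs
    n_out = int(np.floor(values.size / fs / tr))
    t_out = np.arange(n_out) * tr
    out = np.interp(t_out, t_in, conv)
    if kind is None:
        kind = "RVT" if kernel == "RRF" else "HRV"
    return PhysioRegressor(kind=kind, values=out, tr_s=tr, kernel=kernel)


def iqr_outlier_flags(paired_diffs: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Flag between-condition differences outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation (the type-7 default). With all values
    equal, IQR is zero and nothing is flagged (the interval still contains
    the common value).
    """
    d = np.asarray(paired_diffs, dtype=float)
    if d.size < 4:
        raise ValueError("need at least four values for the IQR rule")
    q1, q3 = np.percentile(d, [25, 75])
    iqr = q3 - q1
    return (d < q1 - k * iqr) | (d > q3 + k * iqr)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def bold_physio_coupling(bold_a: np.ndarray, bold_b: np.ndarray,
                         reg_a: np.ndarray, reg_b: np.ndarray,
                         roi_labels: list[str] | None = None) -> pd.DataFrame:
    """Per-ROI comparison of BOLD-physiology coupling between conditions.

    Parameters are (n_subjects, n_samples, n_rois) BOLD arrays and
    (n_subjects, n_samples) regressor arrays for the two conditions. For
    each subject and ROI the Pearson correlation between the regressor and
    the ROI series is Fisher Z-transformed; a paired t-test across subjects
    compares conditions per ROI, with BH-FDR across ROIs. ROIs whose series
    have zero variance in any subject are reported with NaN statistics and
    excluded from the FDR family.
    """
    bold_a = np.asarray(bold_a, dtype=float)
    bold_b = np.asarray(bold_b, dtype=float)
    if bold_a.shape != bold_b.shape:
        raise ValueError("condition arrays must have matching shapes")
    n_sub, _, n_roi = bold_a.shape

    def corr(bold: np.ndarray, reg: np.ndarray) -> np.ndarray:
        out = np.full((n_sub, n_roi), np.nan)
        for s in range(n_sub):
            x = reg[s] - reg[s].mean()
            sx = x.std()
            y = bold[s] - bold[s].mean(axis=0)
            sy = y.std(axis=0)
            ok = (sx > 0) & (sy > 0)
            out[s, ok] = (x @ y[:, ok]) / (x.size * sx * sy[ok])
        return out

    r_a = corr(bold_a, np.asarray(reg_a, dtype=float))
    r_b = corr(bold_b, np.asarray(reg_b, dtype=float))
    z_a, z_b = _fisher_z(r_a), _fisher_z(r_b)
    t = np.full(n_roi, np.nan)
    p = np.full(n_roi, np.nan)
    usable = ~(np.isnan(z_a).any(axis=0) | np.isnan(z_b).any(axis=0))
    diffs = z_a - z_b
    for j in np.where(usable)[0]:
        if np.allclose(diffs[:, j], 0.0):
            t[j], p[j] = 0.0, 1.0
        else:
            t[j], p[j] = ttest_rel(z_a[:, j], z_b[:, j])
    from .connectivity import bh_fdr
    p_fdr = np.full(n_roi, np.nan)
    if usable.any():
        p_fdr[usable] = bh_fdr(p[usable])
    if roi_labels is None:
        roi_labels = [f"ROI{i:03d}" for i in range(n_roi)]
    return pd.DataFrame({
        "roi": roi_labels,
        "r_A": np.nanmean(r_a, axis=0), "r_B": np.nanmean(r_b, axis=0),
        "z_A": np.nanmean(z_a, axis=0), "z_B": np.nanmean(z_b, axis=0),
        "t_paired": t, "p_unc": p, "p_fdr": p_fdr,
    })
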