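"""Band-limiting, resampling, instantaneous phase, and sliding-window PLV.

The phase-locking analysis runs on signals band-limited to 0.1-0.2 Hz (the
intermediate-frequency band centered near 0.16 Hz). Respiration traces are
anti-alias filtered (0.01-0.25 Hz) and downsampled to the BOLD rate before
phase extraction; an alternative non-anti-aliased decimation path exists for
the aliasing control analysis. Instantaneous phase within the band can be
estimated either from the analytic signal of the band-passed trace (Hilbert)
or by complex scale-averaging of a Morlet continuous wavelet transform.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .types import PhaseSeries, PlvSeries

__all__ = [
    "BandSpec",
    "DEFAULT_BAND",
    "bandpass_filter",
    "resample_trace",
    "instantaneous_phase",
    "sliding_plv",
    "plv_window_samples",
]


class BandSpec:
    """Frequency band of interest with its nominal center frequency."""

    def __init__(self, lo: float = 0.1, hi: float = 0.2, center: float | None = None):
        if not (0 < lo < hi):
            raise ValueError("band edges must satisfy 0 < lo < hi")
        self.lo = lo
        self.hi = hi
        self.center = center if center is not None else np.sqrt(lo * hi)
        if not (lo < self.center < hi):
            raise ValueError("center frequency must lie inside the band")

    def __repr__(self) -> str:  # pragma: no cover
        return f"BandSpec({self.lo}, {self.hi}, center={self.center:.3g})"


#: 0.1-0.2 Hz band centered at ~0.16 Hz.
DEFAULT_BAND = BandSpec(0.1, 0.2, 0.16)


def bandpass_filter(x: np.ndarray, fs: float, lo: float, hi: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward).

    Applied along the first axis so multi-ROI matrices filter column-wise.
    Raises if the upper edge reaches the Nyquist frequency.
    """
    x = np.asarray(x, dtype=float)
    if not lo < hi:
        raise ValueError("lo must be below hi")
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"upper band edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return sosfiltfilt(sos, x, axis=0)


def resample_trace(x: np.ndarray, fs: float, fs_target: float,
                   antialias: bool = True) -> np.ndarray:
    """Downsample a uniformly sampled signal to ``fs_target``.

    With ``antialias=True`` the signal is low-passed at 0.8x the target
    Nyquist frequency before linear interpolation onto the target grid. With
    ``antialias=False`` samples are picked by pure nearest-index selection,
    deliberately letting out-of-band components fold into the target band
    (the aliasing-control path).
    """
    x = np.asarray(x, dtype=float)
    if fs_target > fs:
        raise ValueError("fs_target must not exceed fs")
    if fs_target == fs:
        return x.copy()
    n_out = int(np.floor(x.shape[0] * fs_target / fs))
    if antialias:
        cut = 0.8 * (fs_target / 2.0)
        sos = butter(8, cut / (fs / 2.0), btype="lowpass", output="sos")
        y = sosfiltfilt(sos, x, axis=0)
        t_in = np.arange(x.shape[0]) / fs
        t_out = np.arange(n_out) / fs_target
        return np.interp(t_out, t_in, y)
    idx = np.round(np.arange(n_out) * fs / fs_target).astype(int)
    idx = idx[idx < x.shape[0]]
    return x[idx]


def _morlet_cwt(x: np.ndarray, fs: float, freqs: np.ndarray,
                omega0: float = 6.0) -> np.ndarray:
    """Analytic Morlet continuous wavelet transform via the FFT.

    Mother wavelet exp(i*omega0*t) exp(-t^2/2); the scale for pseudo-
    frequency f is s = omega0 / (2*pi*f). Frequency-domain evaluation keeps
    phases exact even at scales of a few samples (time-domain wavelet
    discretization is too coarse at a 2 s TR).
    """
    n = x.size
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=1.0 / fs)
    xf = np.fft.fft(x, n_fft)
    out = np.empty((freqs.size, n), dtype=complex)
    for i, f in enumerate(np.asarray(freqs, dtype=float)):
        s = omega0 / (2.0 * np.pi * f)
        psi = np.zeros(n_fft)
        pos = omega > 0
        psi[pos] = np.pi**-0.25 * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
        out[i] = np.fft.ifft(xf * psi)[:n]
    return out


def _edge_mask(n: int, fs: float, lo: float) -> np.ndarray:
    """Validity mask excluding the cone of influence at each record edge.

    The guard is the Morlet e-folding time at the lowest band frequency,
    sqrt(2) * omega0 / (2 pi lo) ~ 1.35 / lo seconds -- roughly one period
    of the lower band edge.
    """
    guard = int(np.ceil(1.35 * fs / lo))
    valid = np.ones(n, dtype=bool)
    valid[:guard] = False
    valid[n - guard:] = False
    return valid


def instantaneous_phase(x: np.ndarray, fs: float, band: BandSpec = DEFAULT_BAND,
                        method: str = "wavelet", n_scales: int = 12) -> PhaseSeries:
    """Instantaneous phase of ``x`` within ``band``.

    ``method="hilbert"``: analytic-signal phase of the zero-phase band-passed
    trace. ``method="wavelet"``: Morlet (omega0 = 6) CWT coefficients on
    log-spaced scales spanning the band are complex-averaged across scales
    (weighting each time point by in-band energy) before taking the angle.
    Both estimators mark roughly one period of the lower band edge at each
    end of the record as invalid (cone of influence / filter transients).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    guard = int(np.ceil(1.35 * fs / band.lo))
    if n < 2 * guard:
        raise ValueError("trace shorter than twice the edge-exclusion zone")
    if method == "hilbert":
        y = bandpass_filter(x, fs, band.lo, band.hi)
        phi = np.angle(hilbert(y))
    elif method == "wavelet":
        freqs = np.geomspace(band.lo, band.hi, n_scales)
        coefs = _morlet_cwt(x - x.mean(), fs, freqs)
        phi = np.angle(coefs.mean(axis=0))
    else:
        raise ValueError(f"unknown phase method {method!r}")
    return PhaseSeries(phi=phi, fs=fs, valid=_edge_mask(n, fs, band.lo))


def plv_window_samples(fs: float, center_hz: float = 0.16,
                       n_cycles: float = 4.0) -> int:
    """Sliding-window length: ~``n_cycles`` cycles of the band center.

    Four cycles of 0.16 Hz at a 2 s TR give 12.5 samples; rounded to the
    nearest odd integer (13) so the window centers symmetrically.
    """
    n = n_cycles / center_hz * fs
    k = int(round(n))
    if k % 2 == 0:
        k += 1 if n >= k else -1
    return max(k, 5)


def sliding_plv(phase_x: PhaseSeries, phase_y: PhaseSeries,
                window_samples: int) -> PlvSeries:
    """Sliding-window phase-locking value between two phase series.

    PLV at window position t is ``|mean(exp(i*(phi_x - phi_y)))`` over the
    centered window (step one sample). Output bins are valid only where the
    window lies fully inside the record and every contributing sample of
    both inputs is valid.
    """
    if phase_x.phi.shape != phase_y.phi.shape:
        raise ValueError("phase series lengths differ")
    if phase_x.fs != phase_y.fs:
        raise ValueError("phase series sampling rates differ")
    if window_samples < 4:
        raise ValueError("window must span at least 4 samples")
    n = phase_x.phi.size
    z = np.exp(1j * (phase_x.phi - phase_y.phi))
    kernel = np.ones(window_samples)
    plv = np.abs(np.convolve(z, kernel, mode="same")) / window_samples
    both = (phase_x.valid & phase_y.valid).astype(float)
    full = np.convolve(both, kernel, mode="same")
    valid = np.isclose(full, window_samples)
    half = window_samples // 2
    valid[:half] = False
    valid[n - half:] = False
    times = np.arange(n) / phase_x.fs
    return PlvSeries(values=np.clip(plv, 0.0, 1.0),
                     window_samples=window_samples, times=times, valid=valid)
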