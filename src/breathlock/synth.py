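"""Synthetic paired-condition cohort generator.

Emulates the study conditions of a paired nasal/oral resting-state fMRI
experiment: 10-minute runs at TR = 2 s, respiration near 0.31 Hz with a
between-subject SD of ~0.04 Hz, 20 paired subjects, 133 ROIs, and a
condition-dependent hub (an olfactory-like hub in condition A, a
brainstem-like hub in condition B). Every generator is deterministic given
its seed.

Generative model
----------------
* Respiration: quasi-sinusoid whose instantaneous frequency follows an
  Ornstein-Uhlenbeck drift around the subject's base rate; breath amplitudes
  vary breath-by-breath and carry a period-2 (alternate-breath) modulation,
  which places a genuine subharmonic at half the respiratory rate (~0.155 Hz,
  inside the 0.1-0.2 Hz analysis band).
* Cardiac RR intervals: AR(1) jitter around 60000/HR ms scaled so that the
  expected RMSSD matches the requested target.
* BOLD: 1/f + white background noise; coupled ROIs add an oscillation whose
  phase tracks half the unwrapped respiration phase plus von Mises phase
  noise with concentration ``coupling_kappa`` (kappa = 0 means no entrained
  component at all), plus an optional direct respiratory artifact sampled at
  TR (which is therefore aliased, as in real acquisitions).
* Connectivity: per-subject symmetric Fisher-Z matrices = common baseline +
  subject random effect + measurement noise; the active condition's hub row
  and column gain ``effect_z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import default_roi_labels
from .types import CardiacSeries, ConnectivityStack, RespirationTrace, RoiTimeSeries

__all__ = [
    "SimConfig",
    "SubjectRecording",
    "gen_respiration",
    "gen_cardiac_rr",
    "gen_coupled_bold",
    "gen_cohort_connectivity",
    "gen_toy_volume_dataset",
    "gen_cohort",
]


@dataclass
class SimConfig:
    """Parameters of the simulated paired-condition cohort.

    Defaults follow the emulated study: 20 subjects, 600 s runs, TR 2 s,
    respiration at 0.31 +/- 0.04 Hz (between subjects), HR ~69 bpm with an
    RMSSD target of ~17 ms, 133 ROIs with hub 0 ("Olfactory") active in
    condition A and hub 1 ("Brainstem") in condition B.
    """

    n_subjects: int = 20
    duration_s: float = 600.0
    tr_s: float = 2.0
    fs_resp_hz: float = 50.0
    resp_f0_hz: float = 0.31
    resp_f0_sd_hz: float = 0.04
    hr_bpm_mean: float = 69.0
    rmssd_target_ms: float = 17.0
    rmssd_between_sd_ms: float = 6.0
    n_rois: int = 133
    hub_a: int = 0
    hub_b: int = 1
    coupling_kappa: float = 20.0
    effect_z: float = 0.3
    noise_sd: float = 0.6
    seed: int = 0
    # secondary knobs (not part of the headline study conditions)
    baseline_z: float = 0.25
    baseline_sd: float = 0.1
    subject_sd: float = 0.1
    measurement_sd: float = 0.15
    resp_artifact: float = 1.15
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("duration_s", "tr_s", "fs_resp_hz", "resp_f0_hz",
                     "hr_bpm_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.coupling_kappa < 0:
            raise ValueError("coupling_kappa must be >= 0")
        if self.hub_a == self.hub_b:
            raise ValueError("hub_a and hub_b must differ")
        if not self.roi_labels:
            self.roi_labels = default_roi_labels(self.n_rois)

    @property
    def n_bold_samples(self) -> int:
        return int(np.floor(self.duration_s / self.tr_s))


@dataclass
class SubjectRecording:
    """One subject's simulated session under one breathing condition."""

    respiration: RespirationTrace
    cardiac: CardiacSeries
    bold: RoiTimeSeries
    condition: str
    subject_id: str


def gen_respiration(f0: float, f_sd: float, duration_s: float, fs: float,
                    seed: int | np.random.Generator = 0,
                    amp_jitter: float = 0.1,
                    alternation: float = 0.8) -> RespirationTrace:
    """Quasi-periodic respiration trace with OU frequency drift.

    The instantaneous frequency is an Ornstein-Uhlenbeck process with
    stationary SD ``f_sd`` around ``f0`` (correlation time 30 s). Breath
    amplitudes vary by ``amp_jitter`` (lognormal, breath-by-breath) and carry
    a period-2 alternation of depth ``alternation``, producing a genuine
    subharmonic at f0/2. With ``f_sd=0``, ``amp_jitter=0`` and
    ``alternation=0`` the output is a pure sinusoid at ``f0``.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if fs <= 2 * f0:
        raise ValueError(f"sampling rate {fs} Hz too low for f0={f0} Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    dt = 1.0 / fs
    if f_sd > 0:
        tau = 30.0
        a = np.exp(-dt / tau)
        eps = rng.standard_normal(n)
        dev = np.empty(n)
        dev[0] = f_sd * eps[0]
        s = f_sd * np.sqrt(1.0 - a * a)
        for i in range(1, n):
            dev[i] = a * dev[i - 1] + s * eps[i]
        f_inst = np.clip(f0 + dev, 0.2 * f0, 3.0 * f0)
    else:
        f_inst = np.full(n, f0)
    phase = 2.0 * np.pi * np.cumsum(f_inst) * dt
    phase -= phase[0]

    breath_idx = np.floor(phase / (2.0 * np.pi)).astype(int)
    n_breaths = breath_idx.max() + 1
    amps = np.ones(n_breaths)
    if amp_jitter > 0:
        amps *= np.exp(amp_jitter * rng.standard_normal(n_breaths)
                       - 0.5 * amp_jitter**2)
    if alternation > 0:
        # alternate deep/shallow breaths -> subharmonic at f0/2
        amps *= 1.0 + 0.5 * alternation * np.where(np.arange(n_breaths) % 2, 1, -1)
    samples = amps[breath_idx] * np.sin(phase)
    samples -= samples.mean()
    return RespirationTrace(samples=samples, fs=fs, phase=phase)


def gen_cardiac_rr(hr_mean: float, rmssd_target: float, duration_s: float,
                   seed: int | np.random.Generator = 0,
                   rho: float = 0.3) -> CardiacSeries:
    """RR-interval sequence with a prescribed mean HR and RMSSD.

    RR_i = 60000/hr_mean + x_i where x is a stationary AR(1) process with
    lag-1 correlation ``rho`` and variance chosen so that
    E[RMSSD] = sqrt(2 * var * (1 - rho)) equals ``rmssd_target``.
    """
    if hr_mean <= 0:
        raise ValueError("hr_mean must be positive")
    if rmssd_target < 0:
        raise ValueError("rmssd_target must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_rr = 60000.0 / hr_mean
    n = int(np.ceil(duration_s * 1000.0 / mean_rr)) + 8
    if rmssd_target == 0:
        rr = np.full(n, mean_rr)
    else:
        sigma = rmssd_target / np.sqrt(2.0 * (1.0 - rho))
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = sigma * eps[0]
        s = sigma * np.sqrt(1.0 - rho * rho)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + s * eps[i]
        rr = np.clip(mean_rr + x, 0.25 * mean_rr, 4.0 * mean_rr)
    keep = np.searchsorted(np.cumsum(rr), duration_s * 1000.0, side="right")
    return CardiacSeries(rr_ms=rr[:max(keep, 2)])


def _one_over_f_noise(n: int, n_rois: int, rng: np.random.Generator,
                      sd: float, tr_s: float) -> np.ndarray:
    """1/f (power) + white background noise, unit mix, scaled to ``sd``."""
    white = rng.standard_normal((n, n_rois))
    freqs = np.fft.rfftfreq(n, d=tr_s)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = np.fft.rfft(rng.standard_normal((n, n_rois)), axis=0) * shaping[:, None]
    pink = np.fft.irfft(spec, n=n, axis=0)
    pink /= pink.std(axis=0, keepdims=True) + 1e-30
    noise = (white + pink) / np.sqrt(2.0)
    return sd * noise


def _resp_phase_on_grid(resp: RespirationTrace, t_grid: np.ndarray) -> np.ndarray:
    """Unwrapped respiration phase at arbitrary times.

    Uses the generator's ground-truth phase when available, otherwise the
    analytic-signal phase of the trace band-passed around its fundamental.
    """
    if resp.phase is not None:
        phase = resp.phase
    else:
        from scipy.signal import hilbert

        from .phase import bandpass_filter
        y = bandpass_filter(resp.samples, resp.fs, 0.1, min(1.0, resp.fs / 2 * 0.8))
        phase = np.unwrap(np.angle(hilbert(y)))
    return np.interp(t_grid, resp.times, phase)


def gen_coupled_bold(resp: RespirationTrace, n_rois: int, tr: float,
                     coupling_kappa: float,
                     coupled_rois: list[int] | tuple[int, ...],
                     noise_sd: float,
                     seed: int | np.random.Generator = 0,
                     duration_s: float | None = None,
                     osc_amp: float = 1.0,
                     resp_artifact: float = 0.0,
                     roi_labels: list[str] | None = None) -> RoiTimeSeries:
    """ROI BOLD series with respiration-entrained oscillations.

    Coupled ROIs contain ``osc_amp * cos(phi_resp/2 + eta)`` with eta drawn
    i.i.d. von Mises(0, kappa) per TR sample; at kappa = 0 the entrained
    component is omitted entirely (null construction), so coupled and
    uncoupled ROIs are statistically identical. ``resp_artifact`` adds a
    direct respiratory component ``cos(phi_resp)`` sampled at TR -- because
    the respiratory fundamental (~0.31 Hz) exceeds the BOLD Nyquist
    frequency (0.25 Hz), this term is aliased by construction, as in real
    acquisitions.
    """
    coupled_rois = list(coupled_rois)
    if any(r < 0 or r >= n_rois for r in coupled_rois):
        raise ValueError("coupled_rois out of range")
    if coupling_kappa > 0 and not coupled_rois:
        import warnings
        warnings.warn("coupling requested but no coupled ROIs given")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dur = duration_s if duration_s is not None else resp.duration_s
    n_t = int(np.floor(dur / tr))
    t = np.arange(n_t) * tr
    data = _one_over_f_noise(n_t, n_rois, rng, noise_sd, tr)
    phi = _resp_phase_on_grid(resp, t)
    if resp_artifact > 0:
        data += resp_artifact * np.cos(phi)[:, None]
    if coupling_kappa > 0:
        for roi in coupled_rois:
            eta = rng.vonmises(0.0, coupling_kappa, size=n_t)
            data[:, roi] += osc_amp * np.cos(0.5 * phi + eta)
    labels = roi_labels if roi_labels is not None else default_roi_labels(n_rois)
    return RoiTimeSeries(data=data, tr_s=tr, roi_labels=labels)


def gen_cohort_connectivity(cfg: SimConfig) -> tuple[ConnectivityStack,
                                                     ConnectivityStack, dict]:
    """Paired-condition Fisher-Z connectivity stacks with planted hubs.

    Each subject's matrix is a shared symmetric baseline plus a subject
    random effect plus condition-specific measurement noise; condition A
    adds ``effect_z`` to the hub_a row/column, condition B to hub_b's.
    Returns the two stacks and a ground-truth dict.
    """
    rng = np.random.default_rng(cfg.seed)
    r = cfg.n_rois

    def sym(mat: np.ndarray) -> np.ndarray:
        out = (mat + mat.T) / np.sqrt(2.0)
        np.fill_diagonal(out, 0.0)
        return out

    baseline = cfg.baseline_z + cfg.baseline_sd * rng.standard_normal((r, r))
    baseline = sym(baseline)
    stacks = {"A": [], "B": []}
    for _ in range(cfg.n_subjects):
        subj = cfg.subject_sd * rng.standard_normal()
        for cond in ("A", "B"):
            m = baseline + subj + sym(cfg.measurement_sd *
                                      rng.standard_normal((r, r)))
            hub = cfg.hub_a if cond == "A" else cfg.hub_b
            m[hub, :] += cfg.effect_z
            m[:, hub] += cfg.effect_z
            np.fill_diagonal(m, 0.0)
            stacks[cond].append(m)
    truth = {"hub_a": cfg.hub_a, "hub_b": cfg.hub_b, "effect_z": cfg.effect_z}
    return (ConnectivityStack(np.array(stacks["A"]), cfg.roi_labels, "A"),
            ConnectivityStack(np.array(stacks["B"]), cfg.roi_labels, "B"),
            truth)


def gen_toy_volume_dataset(shape: tuple[int, int, int] = (16, 16, 8),
                           n_subjects: int = 20,
                           blob_spec: dict | None = None,
                           seed: int | np.random.Generator = 0,
                           noise_sd: float = 0.15,
                           subject_sd: float = 0.1):
    """Paired voxel-wise Fisher-Z volumes with a planted effect blob.

    ``blob_spec`` has keys ``center`` (voxel triple), ``radius`` (voxels)
    and ``effect`` (Fisher-Z increment added in condition A inside the
    blob). Returns ``(maps_a, maps_b, blob_mask, label_volume)`` where the
    maps are (n_subjects, *shape) arrays and the label volume partitions the
    grid into four slabs ("networks") along the first axis.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if blob_spec is None:
        blob_spec = {"center": tuple(s // 2 for s in shape), "radius": 1.68,
                     "effect": 0.5}
    grid = np.indices(shape).astype(float)
    center = np.asarray(blob_spec["center"], dtype=float)
    dist = np.sqrt(((grid - center[:, None, None, None]) ** 2).sum(axis=0))
    blob = dist <= blob_spec["radius"]
    base = 0.3 + 0.1 * rng.standard_normal(shape)
    maps_a = np.empty((n_subjects, *shape))
    maps_b = np.empty((n_subjects, *shape))
    for s in range(n_subjects):
        subj = subject_sd * rng.standard_normal()
        maps_a[s] = base + subj + noise_sd * rng.standard_normal(shape)
        maps_b[s] = base + subj + noise_sd * rng.standard_normal(shape)
        maps_a[s][blob] += blob_spec["effect"]
    edges = np.linspace(0, shape[0], 5).astype(int)
    labels = np.zeros(shape, dtype=int)
    for k in range(4):
        labels[edges[k]:edges[k + 1]] = k + 1
    return maps_a, maps_b, blob, labels


def gen_cohort(cfg: SimConfig) -> list[SubjectRecording]:
    """Full paired cohort of physiological traces and coupled BOLD series.

    Condition A couples hub_a to respiration, condition B couples hub_b.
    Subject base respiratory rates are drawn once per subject from
    N(resp_f0_hz, resp_f0_sd_hz) and shared across conditions.
    """
    rng = np.random.default_rng(cfg.seed)
    recs: list[SubjectRecording] = []
    for s in range(cfg.n_subjects):
        f0 = max(0.1, rng.normal(cfg.resp_f0_hz, cfg.resp_f0_sd_hz))
        hr = max(35.0, rng.normal(cfg.hr_bpm_mean, 10.0))
        rmssd_s = max(3.0, rng.normal(cfg.rmssd_target_ms,
                                      cfg.rmssd_between_sd_ms))
        for cond in ("A", "B"):
            resp = gen_respiration(f0, cfg.resp_f0_sd_hz, cfg.duration_s,
                                   cfg.fs_resp_hz, seed=rng)
            cardiac = gen_cardiac_rr(hr, rmssd_s, cfg.duration_s, seed=rng)
            hub = cfg.hub_a if cond == "A" else cfg.hub_b
            bold = gen_coupled_bold(resp, cfg.n_rois, cfg.tr_s,
                                    cfg.coupling_kappa, [hub], cfg.noise_sd,
                                    seed=rng, duration_s=cfg.duration_s,
                                    resp_artifact=cfg.resp_artifact,
                                    roi_labels=cfg.roi_labels)
            recs.append(SubjectRecording(respiration=resp, cardiac=cardiac,
                                         bold=bold, condition=cond,
                                         subject_id=f"sub-{s + 1:02d}"))
    return recs
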