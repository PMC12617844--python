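"""Core in-memory containers shared across the analysis stages.

All containers are thin dataclasses around numpy arrays: the physiological
traces carry their own sampling rate, phase series carry a validity mask
(edge / cone-of-influence exclusion), and connectivity stacks carry the ROI
labels so that workbooks written by one run can be consumed by another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RespirationTrace",
    "CardiacSeries",
    "RoiTimeSeries",
    "PhaseSeries",
    "PlvSeries",
    "ConnectivityStack",
    "PhysioSummary",
    "PhysioRegressor",
    "SigBinsResult",
]


@dataclass
class RespirationTrace:
    """Uniformly sampled respiration belt signal.

    Attributes
    ----------
    samples : ndarray
        Signal values, arbitrary units.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    phase : ndarray or None
        Optional ground-truth unwrapped phase of the respiratory cycle in
        radians (populated by the synthetic generator; real recordings leave
        it ``None``).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("respiration trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class CardiacSeries:
    """Cardiac beat-to-beat (RR) interval sequence in milliseconds."""

    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.rr_ms.size and np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be strictly positive")

    @property
    def beat_times_s(self) -> np.ndarray:
        """Beat times in seconds, first beat at the end of the first interval."""
        return np.cumsum(self.rr_ms) / 1000.0


@dataclass
class RoiTimeSeries:
    """BOLD time series sampled on the TR grid, one column per ROI."""

    data: np.ndarray  # (n_samples, n_rois)
    tr_s: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i:03d}" for i in range(self.data.shape[1])]
        if len(self.roi_labels) != self.data.shape[1]:
            raise ValueError("label count does not match ROI count")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")

    @property
    def fs(self) -> float:
        return 1.0 / self.tr_s

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def roi(self, label: str) -> np.ndarray:
        return self.data[:, self.roi_labels.index(label)]


@dataclass
class PhaseSeries:
    """Instantaneous phase in a frequency band, with a validity mask.

    ``phi`` is wrapped to (-pi, pi]; ``valid`` flags samples outside the
    record-edge exclusion zone (cone of influence for the wavelet estimator,
    filter-transient zone for the Hilbert estimator).
    """

    phi: np.ndarray
    fs: float
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.phi.shape != self.valid.shape:
            raise ValueError("phase and validity mask lengths differ")

    @property
    def unwrapped(self) -> np.ndarray:
        return np.unwrap(self.phi)


@dataclass
class PlvSeries:
    """Sliding-window phase-locking values on the BOLD time grid."""

    values: np.ndarray
    window_samples: int
    times: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        v = self.values[self.valid]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("PLV values must lie in [0, 1]")


@dataclass
class ConnectivityStack:
    """Per-subject symmetric Fisher-Z ROI-to-ROI connectivity matrices."""

    data: np.ndarray  # (n_subjects, n_rois, n_rois)
    roi_labels: list[str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError("stack must be (subjects, n_roi, n_roi)")
        if len(self.roi_labels) != self.data.shape[1]:
            raise ValueError("label count does not match matrix size")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class PhysioSummary:
    """Per-recording physiological metrics."""

    rf_hz: float
    hr_bpm: float
    rmssd_ms: float


@dataclass
class PhysioRegressor:
    """Physiological nuisance regressor resampled onto the BOLD grid."""

    kind: str  # "RVT" or "HRV"
    values: np.ndarray
    tr_s: float
    kernel: str  # "RRF" or "CRF"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SigBinsResult:
    """Outcome of the surrogate-thresholded phase-locking test.

    ``percent_sigbins`` is the percentage of valid time bins where the
    observed PLV strictly exceeds the surrogate threshold; a locking effect
    is called reliable when it reaches at least 10%.
    """

    percent_sigbins: float
    threshold: float | np.ndarray
    reliable: bool
    alpha: float = 0.05
    mode: str = "global"
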