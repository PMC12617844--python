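"""Readers and writers for the analysis' on-disk formats.

Physiological traces travel as small CSV files (two columns ``time_s,value``
for belt signals; one column of RR intervals for cardiac series), ROI BOLD
series as TSV (samples x ROIs with a label header), connectivity stacks as
XLSX workbooks (one 133x133 labeled sheet per subject) or per-subject CSV
files, and statistic/label volumes as NIfTI-1. Readers validate rather than
impute: non-monotone time stamps, NaN rows, shape or label mismatches raise.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .labels import match_order
from .types import CardiacSeries, ConnectivityStack, RespirationTrace, RoiTimeSeries

__all__ = [
    "read_trace",
    "write_trace",
    "read_rr",
    "write_rr",
    "read_roi_tsv",
    "write_roi_tsv",
    "read_connectivity_workbook",
    "write_connectivity_workbook",
    "read_volume",
    "write_volume",
    "write_json",
]


def read_trace(path: str | Path, fs: float | None = None) -> RespirationTrace:
    """Read a two-column ``time_s,value`` CSV into a respiration trace.

    The sampling rate comes from the median time step unless ``fs`` is
    given. Mildly non-uniform time stamps are resampled onto a uniform grid
    with a warning; non-monotone time raises.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a 2-column time_s,value CSV "
                         "(line 1 must be a header)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
        raise ValueError(f"{path}: non-finite values")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time stamps are not strictly increasing")
    step = float(np.median(dt))
    rate = fs if fs is not None else 1.0 / step
    if np.max(np.abs(dt - step)) > 0.01 * step:
        import warnings
        warnings.warn(f"{path}: non-uniform time stamps; resampling")
        grid = np.arange(t[0], t[-1], 1.0 / rate)
        v = np.interp(grid, t, v)
        t = grid
    return RespirationTrace(samples=v, fs=rate, t0=float(t[0]))


def write_trace(path: str | Path, trace: RespirationTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.samples}) \
        .to_csv(path, index=False, float_format="%.8g")


def read_rr(path: str | Path) -> CardiacSeries:
    """Read a one-column RR-interval CSV.

    Values are expected in milliseconds; a file whose median value is below
    10 is auto-detected as seconds and converted, with a warning.
    """
    df = pd.read_csv(path)
    rr = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(~np.isfinite(rr)):
        raise ValueError(f"{path}: non-finite RR intervals")
    if np.median(rr) < 10.0:
        import warnings
        warnings.warn(f"{path}: RR values look like seconds; converting to ms")
        rr = rr * 1000.0
    return CardiacSeries(rr_ms=rr)


def write_rr(path: str | Path, cardiac: CardiacSeries) -> None:
    pd.DataFrame({"rr_ms": cardiac.rr_ms}).to_csv(path, index=False,
                                                  float_format="%.6g")


def read_roi_tsv(path: str | Path, tr_s: float) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    data = df.to_numpy(dtype=float)
    if np.isnan(data).any():
        raise ValueError(f"{path}: NaN rows in ROI series")
    return RoiTimeSeries(data=data, tr_s=tr_s, roi_labels=list(df.columns))


def write_roi_tsv(path: str | Path, series: RoiTimeSeries) -> None:
    pd.DataFrame(series.data, columns=series.roi_labels) \
        .to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_connectivity_workbook(path: str | Path, stack: ConnectivityStack,
                                subject_ids: list[str] | None = None) -> None:
    """One labeled n_roi x n_roi sheet per subject (diagonal written as 0)."""
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:02d}" for i in range(stack.n_subjects)]
    with pd.ExcelWriter(path) as xl:
        for s, sid in enumerate(subject_ids):
            mat = np.nan_to_num(stack.data[s], nan=0.0)
            pd.DataFrame(mat, index=stack.roi_labels,
                         columns=stack.roi_labels).to_excel(xl, sheet_name=sid)


def read_connectivity_workbook(path: str | Path,
                               canonical_labels: list[str] | None = None,
                               condition: str = "",
                               atol: float = 1e-6) -> ConnectivityStack:
    """Read a one-sheet-per-subject connectivity workbook.

    Sheets must be square with matching row/column labels; label order is
    normalized to ``canonical_labels`` when given. Asymmetries beyond
    ``atol`` or label mismatches raise.
    """
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    mats = []
    labels_ref: list[str] | None = None
    for name, df in sheets.items():
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"{path}[{name}]: sheet is {df.shape[0]}x"
                             f"{df.shape[1]}, expected square")
        labels = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != labels:
            raise ValueError(f"{path}[{name}]: row/column labels differ")
        m = df.to_numpy(dtype=float)
        if np.nanmax(np.abs(m - m.T)) > atol:
            raise ValueError(f"{path}[{name}]: matrix asymmetry exceeds {atol}")
        if canonical_labels is not None:
            order = match_order(labels, canonical_labels)
            m = m[np.ix_(order, order)]
            labels = list(canonical_labels)
        if labels_ref is None:
            labels_ref = labels
        elif labels != labels_ref:
            raise ValueError(f"{path}[{name}]: label order differs between sheets")
        mats.append(m)
    if not mats:
        raise ValueError(f"{path}: empty workbook")
    return ConnectivityStack(np.array(mats), labels_ref, condition)


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_volume(path: str | Path, data: np.ndarray,
                 affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))


def write_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(payload, indent=2, default=default))
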