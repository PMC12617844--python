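"""Seed-to-voxel cluster-mass permutation inference on small volumes.

A paired t map over subjects' Fisher-Z difference volumes is thresholded at
a voxel-level p (two-sided, default 0.01); suprathreshold voxels are grouped
into clusters by a chosen 3-D neighborhood (6, 18 or 26; opposite-sign
clusters kept separate). Cluster-level significance comes from a sign-flip
permutation null of the maximum cluster mass (and size) per iteration, with
BH-FDR across the observed clusters. Label-wise voxel counting summarizes a
significant-cluster mask against an integer "network" label volume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import t as t_dist

from .connectivity import fisher_z

__all__ = [
    "seed_voxel_maps",
    "paired_t_volume",
    "form_clusters",
    "cluster_mass_permutation",
    "label_counts",
]


def seed_voxel_maps(seed_series: np.ndarray, voxel_series: np.ndarray,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Fisher-Z correlation of a seed time course with every voxel.

    ``seed_series`` is (n_samples,), ``voxel_series`` is (n_samples, *shape).
    Zero-variance voxels come out NaN (and are excluded downstream).
    """
    x = np.asarray(seed_series, dtype=float)
    v = np.asarray(voxel_series, dtype=float)
    if v.shape[0] != x.size:
        raise ValueError("sample counts differ between seed and voxels")
    shape = v.shape[1:]
    v2 = v.reshape(v.shape[0], -1)
    xc = x - x.mean()
    vc = v2 - v2.mean(axis=0)
    sx = xc.std()
    sv = vc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ vc) / (x.size * sx * sv)
    z = fisher_z(r)
    z[sv == 0] = np.nan
    z = z.reshape(shape)
    if mask is not None:
        z = np.where(mask, z, np.nan)
    return z


def _paired_t_from_diffs(diffs: np.ndarray) -> np.ndarray:
    """Voxel-wise one-sample t over axis 0 of (n_subjects, *shape) diffs."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)


def paired_t_volume(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Voxel-wise paired t(n-1) on z_A - z_B."""
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired map stacks must share a shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    return _paired_t_from_diffs(a - b)


_STRUCTURES = {6: ndimage.generate_binary_structure(3, 1),
               18: ndimage.generate_binary_structure(3, 2),
               26: ndimage.generate_binary_structure(3, 3)}


def _clusters_from_t(tvol: np.ndarray, t_thresh: float,
                     connectivity: int) -> list[dict]:
    """Suprathreshold clusters of each sign separately."""
    struct = _STRUCTURES[connectivity]
    out = []
    for sign in (1.0, -1.0):
        supra = (sign * tvol) > t_thresh
        labeled, n_lab = ndimage.label(supra, structure=struct)
        for lab in range(1, n_lab + 1):
            vox = labeled == lab
            absvals = np.abs(tvol[vox])
            peak = tuple(int(v) for v in np.unravel_index(
                np.argmax(np.abs(np.where(vox, tvol, 0.0))), tvol.shape))
            out.append({"size": int(vox.sum()), "mass": float(absvals.sum()),
                        "peak": peak, "sign": int(sign), "mask": vox})
    return sorted(out, key=lambda c: -c["mass"])


def form_clusters(tvol: np.ndarray, df: int, p_voxel: float = 0.01,
                  connectivity: int = 18) -> pd.DataFrame:
    """Cluster table (size, mass, peak, sign) without cluster p-values.

    Voxels pass the two-sided cluster-forming threshold when
    |t| > t_{1 - p_voxel/2, df}; positive and negative clusters are kept
    separate. The returned frame carries each cluster's boolean mask in the
    ``mask`` column.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    t_thresh = float(t_dist.isf(p_voxel / 2.0, df))
    tvol = np.nan_to_num(np.asarray(tvol, dtype=float), nan=0.0)
    clusters = _clusters_from_t(tvol, t_thresh, connectivity)
    return pd.DataFrame(clusters,
                        columns=["size", "mass", "peak", "sign", "mask"])


def cluster_mass_permutation(maps_a: np.ndarray, maps_b: np.ndarray,
                             p_voxel: float = 0.01, connectivity: int = 18,
                             n_iter: int = 10_000,
                             seed: int | np.random.Generator = 0,
                             fdr_q: float = 0.05) -> pd.DataFrame:
    """Cluster inference by sign-flip permutation of paired differences.

    Each iteration flips the sign of whole subjects' difference maps,
    recomputes the t volume, and records the maximum cluster mass and size
    (zero when nothing survives the forming threshold). Observed clusters
    get add-one exceedance p-values against those max-statistic nulls
    (exact enumeration of all 2^n sign patterns when 2^n <= ``n_iter``),
    then BH-FDR across observed clusters, separately for mass and size.
    """
    from .connectivity import bh_fdr

    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired map stacks must share a shape")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    diffs = (a - b).reshape(n, -1)
    shape = a.shape[1:]
    df = n - 1
    t_thresh = float(t_dist.isf(p_voxel / 2.0, df))
    struct = _STRUCTURES[connectivity]

    tvol = _paired_t_from_diffs((a - b))
    observed = _clusters_from_t(np.nan_to_num(tvol, nan=0.0), t_thresh,
                                connectivity)

    exact = 2 ** n <= n_iter
    if exact:
        signs = np.array(np.meshgrid(*[[-1.0, 1.0]] * n,
                                     indexing="ij")).reshape(n, -1).T
    else:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_iter, n))
    n_eff = signs.shape[0]

    sumsq = (diffs ** 2).sum(axis=0)
    means = signs @ diffs / n
    var = (sumsq / n - means ** 2) * n / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_null = means / np.sqrt(var / n)
    t_null = np.nan_to_num(t_null, nan=0.0, posinf=1e12, neginf=-1e12)

    max_mass = np.zeros(n_eff)
    max_size = np.zeros(n_eff)
    for i in range(n_eff):
        tmap = np.abs(t_null[i]).reshape(shape)
        supra = tmap > t_thresh
        if not supra.any():
            continue
        labeled, n_lab = ndimage.label(supra, structure=struct)
        masses = ndimage.sum_labels(tmap, labeled, index=np.arange(1, n_lab + 1))
        sizes = ndimage.sum_labels(supra, labeled, index=np.arange(1, n_lab + 1))
        max_mass[i] = masses.max()
        max_size[i] = sizes.max()

    rows = []
    for c in observed:
        if exact:
            p_mass = float(np.mean(max_mass >= c["mass"] - 1e-9))
            p_size = float(np.mean(max_size >= c["size"]))
        else:
            p_mass = float((1 + np.sum(max_mass >= c["mass"] - 1e-9))
                           / (n_eff + 1))
            p_size = float((1 + np.sum(max_size >= c["size"])) / (n_eff + 1))
        rows.append({"size": c["size"], "mass": c["mass"], "peak": c["peak"],
                     "sign": c["sign"], "p_mass": p_mass, "p_size": p_size,
                     "mask": c["mask"]})
    table = pd.DataFrame(rows, columns=["size", "mass", "peak", "sign",
                                        "p_mass", "p_size", "mask"])
    if len(table):
        table["p_fdr_mass"] = bh_fdr(table["p_mass"].to_numpy())
        table["p_fdr_size"] = bh_fdr(table["p_size"].to_numpy())
        table["significant"] = table["p_fdr_mass"] < fdr_q
    else:
        table["p_fdr_mass"] = table["p_fdr_size"] = []
        table["significant"] = []
    return table


def label_counts(cluster_mask: np.ndarray, label_volume: np.ndarray) -> pd.DataFrame:
    """Voxel counts of a cluster mask within each integer label.

    Returns one row per nonzero label with the count inside the mask and
    the percent of that label's volume covered.
    """
    mask = np.asarray(cluster_mask, dtype=bool)
    labels = np.asarray(label_volume)
    if mask.shape != labels.shape:
        raise ValueError("mask and label volume grids differ")
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        region = labels == lab
        count = int((mask & region).sum())
        rows.append({"label": int(lab), "voxel_count": count,
                     "region_size": int(region.sum()),
                     "pct_region_covered": 100.0 * count / region.sum()})
    return pd.DataFrame(rows)
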