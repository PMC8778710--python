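"""Replicate-scan filtering, SIM-window stitching and cross-sample alignment.

A spectral-stitching DIMS acquisition records several replicate scans per
m/z window.  Processing reduces those to one peak list per sample:

1. :func:`replicate_filter` clusters peaks across the replicate scans of a
   window (greedy, ascending m/z, ppm tolerance) and keeps clusters seen in
   enough distinct scans;
2. :func:`stitch_windows` concatenates windows, resolving duplicates in the
   overlap regions by window-centre proximity;
3. :func:`align_samples` groups peaks across samples (single linkage in ppm
   space) into the features of a :class:`~dimsqc.core_io.PeakMatrix`.

Cluster membership thresholds follow the three-internal-replicate scheme:
a peak must be present in at least ``min_scans`` (= 2) distinct scans and in
at least ``ceil(min_fraction × n_scans)`` of them (``min_fraction`` = 0.6).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core_io import PeakMatrix

__all__ = ["replicate_filter", "stitch_windows", "align_samples"]


def _greedy_clusters(mz: np.ndarray, ppm_tol: float) -> list[list[int]]:
    """Greedy ascending-m/z clustering: a peak joins the open cluster while it
    is within ``ppm_tol`` of the cluster's running mean m/z."""
    order = np.argsort(mz, kind="mergesort")
    clusters: list[list[int]] = []
    mean = None
    for i in order:
        if mean is not None and (mz[i] - mean) / mean * 1e6 <= ppm_tol:
            clusters[-1].append(i)
            members = clusters[-1]
            mean = float(np.mean(mz[members]))
        else:
            clusters.append([i])
            mean = float(mz[i])
    return clusters


def replicate_filter(peaks: pd.DataFrame, ppm_tol: float, min_scans: int = 2,
                     min_fraction: float = 0.6, n_scans: int = 3) -> pd.DataFrame:
    """Collapse replicate scans of each window into one filtered peak list.

    ``peaks`` needs columns ``window_id``, ``scan_index``, ``mz``,
    ``intensity``.  A cluster is retained iff it contains peaks from at
    least ``min_scans`` distinct scans *and* from at least
    ``ceil(min_fraction × n_scans)`` distinct scans.  The retained peak gets
    the intensity-weighted mean m/z and the mean intensity of its members.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if n_scans < min_scans:
        raise ValueError("n_scans must be >= min_scans")
    need = max(min_scans, math.ceil(min_fraction * n_scans))
    out = []
    for wid, grp in peaks.groupby("window_id", sort=True):
        mz = grp["mz"].to_numpy()
        inten = grp["intensity"].to_numpy()
        scan = grp["scan_index"].to_numpy()
        for members in _greedy_clusters(mz, ppm_tol):
            if len(set(scan[members])) < need:
                continue
            w = inten[members]
            out.append((wid,
                        float(np.average(mz[members], weights=w)),
                        float(np.mean(w)),
                        len(set(scan[members]))))
    return pd.DataFrame(out, columns=["window_id", "mz", "intensity", "n_scans"])


def stitch_windows(filtered: pd.DataFrame, windows: pd.DataFrame,
                   ppm_tol: float = 3.0) -> pd.DataFrame:
    """Merge per-window peak lists into one sorted peak list per sample.

    In an overlap region a peak can be recorded by both adjacent windows;
    of any pair of peaks within ``ppm_tol`` the measurement from the window
    whose centre is nearer to the peak's m/z is kept.
    """
    w = windows.sort_values("window_id").reset_index(drop=True)
    lo, hi = w["mz_lo"].to_numpy(), w["mz_hi"].to_numpy()
    if not (np.all(np.diff(lo) > 0) and np.all(np.diff(hi) > 0)):
        raise ValueError("window bounds must be sorted and increasing")
    centre = dict(zip(w["window_id"], (lo + hi) / 2))

    df = filtered.sort_values("mz", kind="mergesort").reset_index(drop=True)
    kept: list[int] = []
    for i in range(len(df)):
        mz_i = df.at[i, "mz"]
        dist_i = abs(mz_i - centre[df.at[i, "window_id"]])
        if kept:
            j = kept[-1]
            mz_j = df.at[j, "mz"]
            if (mz_i - mz_j) / mz_j * 1e6 <= ppm_tol:
                dist_j = abs(mz_j - centre[df.at[j, "window_id"]])
                if dist_i < dist_j:
                    kept[-1] = i
                continue
        kept.append(i)
    return df.loc[kept].drop(columns=["window_id"]).reset_index(drop=True)


def align_samples(peak_lists: dict[str, pd.DataFrame], ppm_tol_align: float = 3.0,
                  samples: pd.DataFrame | None = None) -> PeakMatrix:
    """Align per-sample peak lists into a features × samples matrix.

    Features are single-linkage groups of m/z values across all samples:
    consecutive (sorted) m/z values closer than ``ppm_tol_align`` belong to
    the same feature.  A sample contributes at most one peak per feature
    (nearest m/z to the feature median wins); absent (feature, sample)
    cells are MISSING.  Feature m/z is the median of member m/z.
    """
    if not peak_lists:
        raise ValueError("need at least one sample peak list")
    frames = []
    for sid, df in peak_lists.items():
        f = df[["mz", "intensity"]].copy()
        f["sample_id"] = sid
        frames.append(f)
    allp = pd.concat(frames, ignore_index=True).sort_values(
        "mz", kind="mergesort").reset_index(drop=True)

    mz = allp["mz"].to_numpy()
    gap_ppm = np.diff(mz) / mz[:-1] * 1e6
    group = np.concatenate([[0], np.cumsum(gap_ppm > ppm_tol_align)])
    allp["feature_group"] = group

    sample_ids = list(peak_lists)
    rows = {}
    mz_rep = {}
    for g, grp in allp.groupby("feature_group", sort=True):
        med = float(grp["mz"].median())
        # nearest peak per sample
        grp = grp.assign(dist=(grp["mz"] - med).abs())
        best = grp.sort_values(["dist", "mz"], kind="mergesort").groupby(
            "sample_id", sort=False).head(1)
        fid = f"M{med:.5f}"
        while fid in rows:           # resolve representative-m/z collisions
            fid += "_"
        mz_rep[fid] = med
        rows[fid] = {r.sample_id: r.intensity for r in best.itertuples()}

    intens = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    intens = intens.reindex(columns=sample_ids)
    if samples is None:
        samples = pd.DataFrame({
            "sample_id": sample_ids,
            "class": "biological",
            "plate_id": "TP1",
            "well": "B2",
            "batch_id": "B1",
            "acquisition_order": range(1, len(sample_ids) + 1),
            "extraction_day": 1,
            "plate_extraction_order": 1,
            "deck_position": "a",
        })
    return PeakMatrix(intensities=intens, mz=pd.Series(mz_rep), samples=samples)
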