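"""Internal-standard based sample-outlier screening.

Every sample is expected to contain the spiked internal standard, so an
aberrant IS intensity flags a failed infusion or pipetting error.  Samples
are screened against class-specific robust intervals

    median(IS) ± k × 1.4826 × MAD(IS)

computed separately for intrastudy QCs (k = 3 in workflow-assessment mode)
and study samples (k = 2); the high-throughput mode uses k = 3 for both.
An IS value that is MISSING is treated as a recorded 0 *for this screening
step only* — the IS is expected in every sample, so a missing IS is itself
evidence of failure.  Blanks are never screened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import PeakMatrix

__all__ = ["ThresholdPair", "scaled_mad", "is_thresholds",
           "flag_outlier_samples", "remove_flagged_samples"]

MAD_SCALE = 1.4826  # makes the MAD a consistent SD estimate under normality


@dataclass
class ThresholdPair:
    """Lower/upper IS-intensity acceptance bounds for one sample class."""

    lower: float
    upper: float
    k: float
    class_applied: str
    median: float
    mad_scaled: float


def scaled_mad(values) -> float:
    """1.4826 × median(|x − median(x)|), with MISSING entries counted as 0.

    The scaling factor makes the statistic estimate one standard deviation
    for normally distributed data.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("scaled_mad of an empty list")
    x = np.where(np.isnan(x), 0.0, x)
    return MAD_SCALE * float(np.median(np.abs(x - np.median(x))))


def is_thresholds(is_intensities: pd.Series, classes: pd.Series,
                  k_qc: float = 3.0, k_study: float = 2.0) -> dict[str, ThresholdPair]:
    """Per-class median ± k×MAD screening intervals for the IS intensity.

    ``classes`` maps sample_id → class; thresholds are computed separately
    for the QC and study (biological) classes.  MISSING IS values enter the
    median/MAD as zeros.
    """
    out = {}
    for cls, k in (("QC", k_qc), ("biological", k_study)):
        ids = classes.index[classes == cls]
        if len(ids) == 0:
            continue
        vals = is_intensities.reindex(ids).to_numpy(dtype=float)
        vals = np.where(np.isnan(vals), 0.0, vals)
        if len(vals) < 3:
            warnings.warn(f"class {cls!r} has fewer than 3 samples; "
                          "IS thresholds are unreliable")
        med = float(np.median(vals))
        mad = scaled_mad(vals)
        out[cls] = ThresholdPair(lower=med - k * mad, upper=med + k * mad,
                                 k=k, class_applied=cls, median=med,
                                 mad_scaled=mad)
    return out


def flag_outlier_samples(pm: PeakMatrix, is_feature: str,
                         thresholds: dict[str, ThresholdPair]) -> pd.DataFrame:
    """Screen every non-blank sample against its class's IS interval.

    Returns one row per screened sample: IS intensity (MISSING → 0), the
    applied bounds and the flag decision.  Blanks are excluded by design.
    """
    is_int = pm.intensities.loc[is_feature].fillna(0.0)
    rows = []
    for sid in pm.intensities.columns:
        cls = pm.samples.at[sid, "class"]
        if cls == "blank" or cls not in thresholds:
            continue
        t = thresholds[cls]
        v = float(is_int[sid])
        rows.append({
            "sample_id": sid, "class": cls, "is_intensity": v,
            "lower": t.lower, "upper": t.upper,
            "flagged": bool(v < t.lower or v > t.upper),
        })
    return pd.DataFrame(rows)


def remove_flagged_samples(pm: PeakMatrix, report: pd.DataFrame) -> tuple[PeakMatrix, list[str]]:
    """Drop flagged samples from the matrix (the screening 'rerun' input).

    Raises if screening would empty a whole sample class.
    """
    flagged = list(report.loc[report["flagged"], "sample_id"])
    if not flagged:
        return pm, []
    keep = [s for s in pm.intensities.columns if s not in set(flagged)]
    kept_classes = set(pm.samples.loc[keep, "class"])
    lost = set(pm.samples.loc[flagged, "class"]) - kept_classes
    if lost:
        raise ValueError(f"screening removed every sample of class(es) {sorted(lost)}")
    return pm.subset(samples=keep), flagged
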