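"""Mass-accuracy drift detection and correction.

Over a multi-day acquisition the instrument's mass accuracy can drift.  The
internal standard, present in every sample, provides a per-sample ppm error
measurement against its known m/z; a cubic smoothing spline fitted to
(acquisition order, ppm error) — with the smoothing parameter selected by
explicit leave-one-out cross-validation over a log-spaced grid — models the
drift, and each sample's m/z values are corrected multiplicatively:

    mz_corrected = mz / (1 + predicted_ppm(order) / 1e6)

Correction is applied per sample, before cross-sample alignment.  A spiked
standards mixture spanning the measured m/z range verifies that the drift
is mass-wide rather than a quirk of a single feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import pearsonr

from .mass import ppm_error

__all__ = ["DriftModel", "extract_is_mz_series", "fit_drift_spline",
           "apply_mz_correction", "verify_drift_with_standards"]

#: log-spaced smoothing-parameter grid, near-interpolation → near-linear
DEFAULT_LAMBDA_GRID = tuple(np.geomspace(1e-3, 1e8, 12))


@dataclass
class DriftModel:
    """A fitted acquisition-order → ppm-error smoothing spline."""

    spline: object
    lam: float
    loocv_curve: pd.Series           # LOOCV MSE per candidate lambda
    order_range: tuple[float, float]

    def predict(self, order) -> np.ndarray:
        """Predicted ppm error; constant extrapolation outside the fitted
        range (with a warning)."""
        x = np.asarray(order, dtype=float)
        lo, hi = self.order_range
        if np.any(x < lo) or np.any(x > hi):
            warnings.warn("acquisition order outside fitted range; "
                          "extrapolating constant from nearest endpoint")
        return np.asarray(self.spline(np.clip(x, lo, hi)), dtype=float)


def extract_is_mz_series(observed_mz: pd.Series, expected_mz: float,
                         acquisition_order: pd.Series,
                         min_points: int = 10) -> pd.DataFrame:
    """Per-sample IS ppm-error series, sorted by acquisition order.

    Samples lacking an IS measurement (NaN m/z) are skipped with a warning.
    Raises when fewer than ``min_points`` usable points remain.
    """
    df = pd.DataFrame({"order": acquisition_order,
                       "observed_mz": observed_mz}).dropna()
    if len(df) < len(acquisition_order.dropna()):
        skipped = sorted(set(acquisition_order.index) - set(df.index))
        warnings.warn(f"samples without IS m/z skipped: {skipped}")
    if len(df) < min_points:
        raise ValueError("insufficient data for drift fit "
                         f"({len(df)} points < {min_points})")
    df["ppm"] = ppm_error(df["observed_mz"].to_numpy(), expected_mz)
    return df.sort_values("order")[["order", "ppm"]]


def _loocv_mse(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    err = np.empty(len(x))
    for i in range(len(x)):
        mask = np.ones(len(x), dtype=bool)
        mask[i] = False
        sp = make_smoothing_spline(x[mask], y[mask], lam=lam)
        err[i] = y[i] - sp(x[i])
    return float(np.mean(err**2))


def fit_drift_spline(series: pd.DataFrame,
                     smoothing_grid=DEFAULT_LAMBDA_GRID) -> DriftModel:
    """Fit a cubic smoothing spline with LOOCV-selected smoothing.

    ``series`` has columns ``order`` and ``ppm``.  For each candidate
    smoothing parameter the mean squared leave-one-out prediction error is
    computed by refitting on n−1 points; the minimizer is refitted on the
    full series and returned together with the whole error curve.
    """
    x = series["order"].to_numpy(dtype=float)
    y = series["ppm"].to_numpy(dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("degenerate series: need >= 4 distinct orders")
    if len(smoothing_grid) < 2:
        raise ValueError("smoothing grid needs >= 2 candidates")
    idx = np.argsort(x, kind="mergesort")
    x, y = x[idx], y[idx]
    curve = pd.Series({lam: _loocv_mse(x, y, lam) for lam in smoothing_grid})
    lam_best = float(curve.idxmin())
    spline = make_smoothing_spline(x, y, lam=lam_best)
    return DriftModel(spline=spline, lam=lam_best, loocv_curve=curve,
                      order_range=(float(x[0]), float(x[-1])))


def apply_mz_correction(mz_values, acquisition_order, model: DriftModel):
    """Remove the modelled ppm drift from m/z measurements.

    ``mz_values`` may be a Series (one value per sample, aligned with
    ``acquisition_order``) or a DataFrame of features × samples; the
    per-sample predicted ppm error is divided out multiplicatively.
    """
    pred = model.predict(np.asarray(acquisition_order, dtype=float))
    factor = 1.0 + pred / 1e6
    if isinstance(mz_values, pd.DataFrame):
        return mz_values / factor[None, :]
    return mz_values / factor


def verify_drift_with_standards(standards_ppm: dict[str, pd.DataFrame],
                                model: DriftModel,
                                r_threshold: float = 0.7) -> pd.DataFrame:
    """Check that the IS drift model matches the spiked standards' trends.

    ``standards_ppm`` maps standard id → (order, ppm) series.  Each series
    is correlated (Pearson) with the model's prediction at the same orders;
    a standard passes at ``r >= r_threshold``.  The report carries a
    ``status`` column: ``verified`` / ``partial`` (one standard only) /
    ``not verified`` (none found).
    """
    if not standards_ppm:
        return pd.DataFrame(columns=["standard", "r", "passed", "status"])
    status = "verified" if len(standards_ppm) >= 2 else "partial"
    rows = []
    for name, ser in standards_ppm.items():
        pred = model.predict(ser["order"].to_numpy(dtype=float))
        obs = ser["ppm"].to_numpy(dtype=float)
        if np.std(pred) == 0 or np.std(obs) == 0:
            r = 0.0
        else:
            r = float(pearsonr(obs, pred).statistic)
        rows.append({"standard": name, "r": r,
                     "passed": bool(r >= r_threshold), "status": status})
    return pd.DataFrame(rows)
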