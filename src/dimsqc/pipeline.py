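"""Filter / normalise / transform cascade for aligned peak matrices.

Stage order (workflow-assessment mode):

    blank subtraction → presence filter (all samples) → sparse-sample
    removal → QC presence filter → PQN → QC-RSD filter
    → {metrics branch: un-imputed matrix}
    → {multivariate branch: kNN imputation → glog → mean centring → PCA
       outlier pass, with one rerun of the cascade after PCA removals}

High-throughput mode additionally runs a QC-anchored signal-intensity drift
correction (after the QC presence filter, before PQN) and uses looser
presence/sparsity thresholds.  Every stage records (features_in,
features_out, samples_in, samples_out) and its parameters in a provenance
log.  "Present" means non-MISSING — a recorded zero counts as present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import minimize_scalar
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import nan_euclidean_distances

from .core_io import PeakMatrix

__all__ = ["PipelineConfig", "ProcessResult", "blank_subtract",
           "presence_filter_all", "remove_sparse_samples", "qc_presence_filter",
           "pqn_normalize", "signal_drift_correct", "rsd_filter", "impute_knn",
           "glog", "glog_transform", "optimize_glog_lambda", "mean_center",
           "pca_outlier_pass", "process_matrix"]


@dataclass
class PipelineConfig:
    """Thresholds of the filter cascade.

    Assessment-mode defaults: 80% overall presence, 30% sample sparsity,
    70% QC presence, 30% QC RSD, kNN k=5, 95% PCA confidence.  HT mode
    switches to 50% presence, 40–50% sparsity and enables the QC-based
    signal-drift correction.
    """

    blank_fold: float = 10.0
    blank_stat: str = "mean"              # mean | median comparison vs blanks
    presence_all_fraction: float = 0.80
    sample_missing_max: float = 0.30
    qc_presence_fraction: float = 0.70
    rsd_max_qc: float = 30.0
    knn_k: int = 5
    glog_lambda: float | None = None      # None → ML-optimised on QCs
    glog_lambda_fallback: float = 1.0
    pca_ci: float = 0.95
    signal_drift_enabled: bool = False
    signal_drift_lambda_grid: tuple = (1e0, 1e2, 1e4, 1e6)
    pqn_reference: str = "qc_median"      # qc_median | all_median

    @classmethod
    def assessment(cls) -> "PipelineConfig":
        return cls()

    @classmethod
    def ht(cls, assay: str = "polar_pos") -> "PipelineConfig":
        """High-throughput thresholds: 50% presence, assay-specific
        sample-sparsity limits (40% polar positive, 50% otherwise)."""
        return cls(presence_all_fraction=0.50,
                   sample_missing_max=0.40 if assay == "polar_pos" else 0.50,
                   signal_drift_enabled=True)


def _counts(pm: PeakMatrix) -> dict:
    return {"features": pm.n_features, "samples": pm.n_samples}


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def blank_subtract(pm: PeakMatrix, blank_fold: float = 10.0,
                   stat: str = "mean") -> tuple[PeakMatrix, dict]:
    """Remove features not sufficiently above the extraction blanks.

    A feature is retained iff its mean (or median) over non-blank samples is
    at least ``blank_fold`` × its mean over blanks; features never seen in
    any blank are always retained.  Blank columns are then dropped.
    """
    blanks = pm.sample_ids("blank")
    rec = {"stage": "blank_subtract", "blank_fold": blank_fold, "stat": stat,
           **{k + "_in": v for k, v in _counts(pm).items()}}
    if not blanks:
        warnings.warn("no blank samples: blank subtraction skipped")
        rec.update(skipped=True, features_out=pm.n_features,
                   samples_out=pm.n_samples)
        return pm, rec
    non_blank = [s for s in pm.intensities.columns if s not in set(blanks)]
    agg = (pd.DataFrame.mean if stat == "mean" else pd.DataFrame.median)
    blank_level = agg(pm.intensities[blanks], axis=1)
    sample_level = agg(pm.intensities[non_blank], axis=1)
    keep = blank_level.isna() | (sample_level >= blank_fold * blank_level)
    out = pm.subset(features=pm.mz.index[keep], samples=non_blank)
    rec.update(features_out=out.n_features, samples_out=out.n_samples,
               removed_features=int((~keep).sum()))
    return out, rec


def presence_filter_all(pm: PeakMatrix, fraction: float) -> tuple[PeakMatrix, dict]:
    """Keep features present (non-MISSING) in at least ``fraction`` of all
    samples (study samples and intrastudy QCs)."""
    present = pm.intensities.notna().mean(axis=1)
    keep = present >= fraction
    out = pm.subset(features=pm.mz.index[keep])
    rec = {"stage": "presence_filter_all", "fraction": fraction,
           "features_in": pm.n_features, "features_out": out.n_features,
           "samples_in": pm.n_samples, "samples_out": out.n_samples}
    return out, rec


def remove_sparse_samples(pm: PeakMatrix, max_missing: float) -> tuple[PeakMatrix, dict]:
    """Drop samples whose MISSING fraction strictly exceeds ``max_missing``."""
    frac = pm.intensities.isna().mean(axis=0)
    keep = frac <= max_missing
    if not keep.any():
        raise ValueError("sparse-sample filter would remove every sample")
    out = pm.subset(samples=pm.intensities.columns[keep])
    rec = {"stage": "remove_sparse_samples", "max_missing": max_missing,
           "features_in": pm.n_features, "features_out": out.n_features,
           "samples_in": pm.n_samples, "samples_out": out.n_samples,
           "removed_samples": list(pm.intensities.columns[~keep])}
    return out, rec


def qc_presence_filter(pm: PeakMatrix, fraction: float = 0.70) -> tuple[PeakMatrix, dict]:
    """Keep features present in at least ``fraction`` of intrastudy QCs."""
    qcs = pm.sample_ids("QC")
    if not qcs:
        raise ValueError("QC presence filter needs QC samples")
    present = pm.intensities[qcs].notna().mean(axis=1)
    keep = present >= fraction
    out = pm.subset(features=pm.mz.index[keep])
    rec = {"stage": "qc_presence_filter", "fraction": fraction,
           "features_in": pm.n_features, "features_out": out.n_features,
           "samples_in": pm.n_samples, "samples_out": out.n_samples}
    return out, rec


# ---------------------------------------------------------------------------
# normalisation / drift
# ---------------------------------------------------------------------------

def pqn_normalize(pm: PeakMatrix, reference: str = "qc_median"
                  ) -> tuple[PeakMatrix, dict]:
    """Probabilistic quotient normalisation.

    The reference spectrum is the per-feature median over intrastudy QCs
    (or over all samples).  Each sample is divided by the median of its
    feature-wise quotients against the reference, computed over co-present
    features with a positive reference value.
    """
    ref_cols = pm.sample_ids("QC") if reference == "qc_median" else \
        list(pm.intensities.columns)
    if reference == "qc_median" and len(ref_cols) < 3:
        raise ValueError("PQN needs >= 3 QC samples for the reference spectrum")
    ref = pm.intensities[ref_cols].median(axis=1)
    if not (ref > 0).any():
        raise ValueError("PQN reference spectrum is empty or all zero")
    out = pm.copy()
    factors = {}
    usable = ref > 0
    for sid in out.intensities.columns:
        x = out.intensities[sid]
        q = (x[usable] / ref[usable]).dropna()
        q = q[q > 0]
        f = float(q.median()) if len(q) else 1.0
        if not np.isfinite(f) or f <= 0:
            f = 1.0
        out.intensities[sid] = x / f
        factors[sid] = f
    rec = {"stage": "pqn_normalize", "reference": reference,
           "features_in": pm.n_features, "features_out": out.n_features,
           "samples_in": pm.n_samples, "samples_out": out.n_samples,
           "factors": factors}
    return out, rec


def _qc_curve(orders: np.ndarray, values: np.ndarray, grid) -> object | None:
    """LOOCV-selected smoothing spline through QC log-intensities, or None
    when fitting is impossible."""
    if len(orders) < 4 or len(np.unique(orders)) < 4:
        return None
    idx = np.argsort(orders, kind="mergesort")
    x, y = orders[idx], np.log(values[idx])
    best, best_err = None, np.inf
    for lam in grid:
        err = 0.0
        for i in range(len(x)):
            m = np.ones(len(x), dtype=bool)
            m[i] = False
            sp = make_smoothing_spline(x[m], y[m], lam=lam)
            err += float(y[i] - sp(x[i])) ** 2
        if err < best_err:
            best_err, best = err, lam
    return make_smoothing_spline(x, y, lam=best)


def signal_drift_correct(pm: PeakMatrix, lambda_grid=(1e0, 1e2, 1e4, 1e6)
                         ) -> tuple[PeakMatrix, dict]:
    """QC-anchored intensity-drift correction, per feature and batch.

    For each (feature, batch) a smoothing curve (spline + LOOCV on the log
    scale) is fitted to the QC intensities against acquisition order; all
    samples in the batch are divided by the curve at their order and
    rescaled to the batch QC median.  Features (or whole batches with < 4
    QCs) where the fit is impossible fall back to batch-median scaling
    against the overall QC median.
    """
    qcs = set(pm.sample_ids("QC"))
    out = pm.copy()
    n_curve, n_fallback = 0, 0
    orders = pm.samples["acquisition_order"]
    global_med = pm.intensities[list(qcs)].median(axis=1)
    for batch, meta in pm.samples.groupby("batch_id"):
        cols = list(meta.index)
        qc_cols = [c for c in cols if c in qcs]
        batch_orders = orders[cols].to_numpy(dtype=float)
        if len(qc_cols) < 4:
            warnings.warn(f"batch {batch}: fewer than 4 QCs, "
                          "falling back to batch-median scaling")
        for fid in pm.intensities.index:
            qv = pm.intensities.loc[fid, qc_cols].dropna()
            curve = None
            if len(qc_cols) >= 4 and len(qv) >= 4:
                curve = _qc_curve(orders[qv.index].to_numpy(dtype=float),
                                  qv.to_numpy(dtype=float), lambda_grid)
            batch_med = float(qv.median()) if len(qv) else np.nan
            x = out.intensities.loc[fid, cols]
            if curve is not None and np.isfinite(batch_med) and batch_med > 0:
                fitted = np.exp(np.asarray(curve(batch_orders), dtype=float))
                out.intensities.loc[fid, cols] = x / fitted * batch_med
                n_curve += 1
            elif np.isfinite(batch_med) and batch_med > 0 \
                    and np.isfinite(global_med[fid]) and global_med[fid] > 0:
                out.intensities.loc[fid, cols] = x / batch_med * global_med[fid]
                n_fallback += 1
    rec = {"stage": "signal_drift_correct", "curve_fits": n_curve,
           "fallbacks": n_fallback,
           "features_in": pm.n_features, "features_out": out.n_features,
           "samples_in": pm.n_samples, "samples_out": out.n_samples}
    return out, rec


def rsd_filter(pm: PeakMatrix, rsd_max: float = 30.0) -> tuple[PeakMatrix, dict]:
    """Remove features whose RSD across intrastudy QCs exceeds ``rsd_max`` %.

    Features with fewer than two QC measurements cannot demonstrate
    repeatability and are removed as failing.
    """
    qcs = pm.sample_ids("QC")
    if not qcs:
        raise ValueError("RSD filter needs QC samples")
    qvals = pm.intensities[qcs]
    n = qvals.notna().sum(axis=1)
    mean = qvals.mean(axis=1)
    sd = qvals.std(axis=1, ddof=1)
    rsd = sd / mean * 100.0
    keep = (n >= 2) & mean.gt(0) & rsd.le(rsd_max)
    out = pm.subset(features=pm.mz.index[keep])
    rec = {"stage": "rsd_filter", "rsd_max": rsd_max,
           "features_in": pm.n_features, "features_out": out.n_features,
           "samples_in": pm.n_samples, "samples_out": out.n_samples}
    return out, rec


# ---------------------------------------------------------------------------
# multivariate branch
# ---------------------------------------------------------------------------

def impute_knn(pm: PeakMatrix, k: int = 5) -> tuple[PeakMatrix, dict]:
    """k-nearest-neighbour imputation of MISSING cells (k = 5 by default).

    Sample-sample distances are Euclidean over co-present features on the
    standardised matrix; a MISSING (feature, sample) cell becomes the mean
    of the feature over the k nearest samples in which it was measured.
    Deterministic given the matrix.
    """
    X = pm.intensities.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    if k >= n_samp:
        warnings.warn(f"k={k} >= n_samples={n_samp}; clamped to {n_samp - 1}")
        k = n_samp - 1
    mu = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    D = nan_euclidean_distances(Z.T, Z.T)
    np.fill_diagonal(D, np.inf)
    out = X.copy()
    miss_f, miss_s = np.where(np.isnan(X))
    for f, s in zip(miss_f, miss_s):
        has = ~np.isnan(X[f])
        cand = np.where(has)[0]
        cand = cand[np.isfinite(D[s, cand])]
        if len(cand) == 0:
            out[f, s] = np.nanmean(X[f]) if has.any() else 0.0
            continue
        nearest = cand[np.argsort(D[s, cand], kind="mergesort")[:k]]
        out[f, s] = float(np.mean(X[f, nearest]))
    pm2 = pm.copy()
    pm2.intensities = pd.DataFrame(out, index=pm.intensities.index,
                                   columns=pm.intensities.columns)
    rec = {"stage": "impute_knn", "k": k, "imputed_cells": int(len(miss_f)),
           "features_in": pm.n_features, "features_out": pm.n_features,
           "samples_in": pm.n_samples, "samples_out": pm.n_samples}
    return pm2, rec


def glog(x, lam: float):
    """Generalised logarithm ``ln((x + sqrt(x² + λ)) / 2)``; at λ = 0 this
    is ln(x)."""
    if lam < 0:
        raise ValueError("glog lambda must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.log((x + np.sqrt(x**2 + lam)) / 2.0)


def optimize_glog_lambda(qc_values: np.ndarray) -> float:
    """Maximum-likelihood λ on QC replicates (variance stabilisation).

    Profile log-likelihood of the transformed data under a per-feature-mean,
    common-variance Gaussian model, including the Jacobian of the transform:
    maximise  −N/2·log(RSS/N) − ½·Σ log(x² + λ).
    """
    X = np.asarray(qc_values, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    if X.size == 0 or X.shape[1] < 2:
        raise ValueError("glog optimisation needs complete QC replicates")
    N = X.size
    scale = max(float(np.nanmedian(X)), 1.0)

    def neg_loglik(log_lam: float) -> float:
        lam = 10.0 ** log_lam
        Z = glog(X, lam)
        rss = float(((Z - Z.mean(axis=1, keepdims=True)) ** 2).sum())
        rss = max(rss, 1e-300)
        return N / 2 * np.log(rss / N) + 0.5 * float(np.log(X**2 + lam).sum())

    res = minimize_scalar(neg_loglik, bounds=(-2, 2 * np.log10(scale) + 4),
                          method="bounded")
    return float(10.0 ** res.x)


def glog_transform(pm: PeakMatrix, lam: float | None = None,
                   lambda_fallback: float = 1.0) -> tuple[PeakMatrix, dict]:
    """Apply the generalised log transform; λ is ML-optimised on the QC
    samples unless given, falling back to ``lambda_fallback``."""
    chosen = lam
    if chosen is None:
        qcs = pm.sample_ids("QC")
        try:
            chosen = optimize_glog_lambda(pm.intensities[qcs].to_numpy())
        except ValueError:
            warnings.warn("glog lambda optimisation failed; using fallback")
            chosen = lambda_fallback
    out = pm.copy()
    out.transformed = True
    out.intensities = pd.DataFrame(glog(pm.intensities.to_numpy(), chosen),
                                   index=pm.intensities.index,
                                   columns=pm.intensities.columns)
    rec = {"stage": "glog_transform", "lambda": float(chosen),
           "features_in": pm.n_features, "features_out": pm.n_features,
           "samples_in": pm.n_samples, "samples_out": pm.n_samples}
    return out, rec


def mean_center(pm: PeakMatrix) -> tuple[PeakMatrix, dict]:
    """Subtract each feature's mean: every row of the result has mean 0."""
    out = pm.copy()
    out.transformed = True
    out.intensities = pm.intensities.sub(pm.intensities.mean(axis=1), axis=0)
    rec = {"stage": "mean_center",
           "features_in": pm.n_features, "features_out": pm.n_features,
           "samples_in": pm.n_samples, "samples_out": pm.n_samples}
    return out, rec


def pca_outlier_pass(pm: PeakMatrix, ci: float = 0.95
                     ) -> tuple[list[str], pd.DataFrame]:
    """Flag multivariate sample outliers with Hotelling's T² on 2 PCs.

    A sample is flagged when its T² over the first two principal components
    exceeds the F-distribution critical value at confidence ``ci``:
    T² > 2(n−1)/(n−2) · F_{ci}(2, n−2).  Needs a centred, complete matrix.
    """
    X = pm.intensities.to_numpy(dtype=float).T  # samples × features
    n = X.shape[0]
    if n < 5:
        warnings.warn("PCA outlier pass skipped: fewer than 5 samples")
        return [], pd.DataFrame(columns=["sample_id", "t2", "flagged"])
    k = 2
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    var = pca.explained_variance_
    var = np.where(var <= 0, np.inf, var)
    t2 = (scores**2 / var).sum(axis=1)
    if ci >= 1.0:
        crit = np.inf
    else:
        crit = k * (n - 1) / (n - k) * sps.f.ppf(ci, k, n - k)
    df = pd.DataFrame({"sample_id": pm.intensities.columns, "t2": t2,
                       "flagged": t2 > crit})
    return list(df.loc[df["flagged"], "sample_id"]), df


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

@dataclass
class ProcessResult:
    """Output of the cascade: checkpoint matrices + provenance."""

    after_pqn: PeakMatrix
    after_rsd: PeakMatrix
    multivariate: PeakMatrix | None
    pca_flagged: list[str]
    stages: list[dict] = field(default_factory=list)

    @property
    def feature_counts(self) -> dict[str, int]:
        return {s["stage"]: s["features_out"] for s in self.stages
                if "features_out" in s}


def _cascade_once(pm: PeakMatrix, cfg: PipelineConfig, stages: list[dict]
                  ) -> tuple[PeakMatrix, PeakMatrix]:
    pm, rec = blank_subtract(pm, cfg.blank_fold, cfg.blank_stat)
    stages.append(rec)
    pm, rec = presence_filter_all(pm, cfg.presence_all_fraction)
    stages.append(rec)
    pm, rec = remove_sparse_samples(pm, cfg.sample_missing_max)
    stages.append(rec)
    pm, rec = qc_presence_filter(pm, cfg.qc_presence_fraction)
    stages.append(rec)
    if cfg.signal_drift_enabled:
        pm, rec = signal_drift_correct(pm, cfg.signal_drift_lambda_grid)
        stages.append(rec)
    pm, rec = pqn_normalize(pm, cfg.pqn_reference)
    rec = {k: v for k, v in rec.items() if k != "factors"}
    stages.append(rec)
    after_pqn = pm
    pm, rec = rsd_filter(pm, cfg.rsd_max_qc)
    stages.append(rec)
    return after_pqn, pm


def _pca_flags_by_class(mv: PeakMatrix, ci: float) -> list[str]:
    """PCA outlier pass run within each sample class.

    Pooled QCs and biological samples have different multivariate centres
    by design, so a single T² over the mixed population would flag the
    smaller class wholesale; screening each class against its own PCA model
    flags genuinely aberrant samples only.
    """
    flagged: list[str] = []
    for cls in ("QC", "biological"):
        ids = mv.sample_ids(cls)
        if len(ids) < 5:
            continue
        fl, _ = pca_outlier_pass(mv.subset(samples=ids), ci)
        flagged.extend(fl)
    return flagged


def process_matrix(pm: PeakMatrix, cfg: PipelineConfig | None = None,
                   multivariate: bool = True) -> ProcessResult:
    """Run the full cascade, including the PCA outlier pass with one rerun.

    The metrics/statistics branch uses the un-imputed post-RSD-filter
    matrix; the multivariate branch is imputed, glog-transformed, centred
    and screened by PCA (per sample class).  When PCA flags samples, the
    whole cascade is rerun once from blank subtraction without them.
    """
    cfg = cfg or PipelineConfig()
    stages: list[dict] = []
    after_pqn, after_rsd = _cascade_once(pm, cfg, stages)
    mv = None
    flagged: list[str] = []
    if multivariate:
        mv, rec = impute_knn(after_rsd, cfg.knn_k)
        stages.append(rec)
        mv, rec = glog_transform(mv, cfg.glog_lambda, cfg.glog_lambda_fallback)
        stages.append(rec)
        mv, rec = mean_center(mv)
        stages.append(rec)
        flagged = _pca_flags_by_class(mv, cfg.pca_ci)
        stages.append({"stage": "pca_outlier_pass", "ci": cfg.pca_ci,
                       "flagged_samples": flagged})
        if flagged:
            keep = [s for s in pm.intensities.columns if s not in set(flagged)]
            stages.append({"stage": "pca_rerun", "removed": flagged})
            pm2 = pm.subset(samples=keep)
            after_pqn, after_rsd = _cascade_once(pm2, cfg, stages)
            mv, rec = impute_knn(after_rsd, cfg.knn_k)
            stages.append(rec)
            mv, rec = glog_transform(mv, cfg.glog_lambda,
                                     cfg.glog_lambda_fallback)
            stages.append(rec)
            mv, rec = mean_center(mv)
            stages.append(rec)
    return ProcessResult(after_pqn=after_pqn, after_rsd=after_rsd,
                         multivariate=mv, pca_flagged=flagged, stages=stages)
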