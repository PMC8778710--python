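"""Repeatability metrics and per-feature condition statistics.

Quality metrics follow the median-RSD convention: per-feature relative
standard deviation (SD/mean × 100) within a sample class, summarised as the
median over features (mRSD), reported per plate and per class, with a 30%
criterion for biological control samples and a 20% guidance for intrastudy
QCs.

Condition comparisons use one-way ANOVA on ln intensities with
Benjamini-Hochberg FDR control, Tukey-Kramer post-hoc tests (studentized
range with the unbalanced harmonic-mean correction) and geometric-mean fold
changes.  A feature is "not repeatable" for a group pair iff its
FDR-adjusted ANOVA p ≤ 0.05, post-hoc p ≤ 0.05 and its fold change is
outside [1/1.2, 1.2].  Only features detected in at least three replicates
per group are eligible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import PeakMatrix

__all__ = ["StatResult", "feature_rsd", "mrsd", "per_plate_mrsd",
           "anova_posthoc", "geometric_fold_change", "classify_not_repeatable",
           "welch_edge_centre", "is_rsd_report", "tukey_kramer"]

P_MAX = 0.05
FC_GATE = 1.2
MIN_REPLICATES = 3


def feature_rsd(values) -> float:
    """Relative standard deviation (%) of one feature: SD/mean × 100.

    Needs ≥ 2 non-MISSING values and a positive mean; otherwise NaN.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return float("nan")
    m = float(np.mean(x))
    if m <= 0:
        return float("nan")
    return float(np.std(x, ddof=1) / m * 100.0)


def mrsd(pm: PeakMatrix, sample_ids) -> float:
    """Median over features of the per-feature RSD within ``sample_ids``.

    Features with undefined RSD (fewer than two values, non-positive mean)
    are excluded from the median.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("mrsd of an empty sample subset")
    sub = pm.intensities[sample_ids]
    n = sub.notna().sum(axis=1)
    mean = sub.mean(axis=1)
    rsd = sub.std(axis=1, ddof=1) / mean * 100.0
    rsd = rsd[(n >= 2) & (mean > 0)].dropna()
    if rsd.empty:
        raise ValueError("no feature has >= 2 values in the subset")
    return float(rsd.median())


def per_plate_mrsd(pm: PeakMatrix, checkpoints: dict[str, PeakMatrix],
                   mrsd_max: float = 30.0) -> pd.DataFrame:
    """Per-plate mRSD of biological samples at each cascade checkpoint.

    ``checkpoints`` maps a label (e.g. ``after_pqn``, ``after_rsd_filter``)
    to the matrix at that point.  Plates with < 2 samples are skipped.
    Each row carries a pass/fail flag against the ``mrsd_max`` criterion.
    """
    rows = []
    bio = pm.samples[pm.samples["class"] == "biological"]
    for plate, meta in bio.groupby("plate_id"):
        for label, mat in checkpoints.items():
            ids = [s for s in meta.index if s in mat.intensities.columns]
            if len(ids) < 2:
                continue
            v = mrsd(mat, ids)
            rows.append({"plate_id": plate, "checkpoint": label, "n": len(ids),
                         "mrsd": v, "passed": bool(v <= mrsd_max)})
    return pd.DataFrame(rows)


def geometric_fold_change(group_a, group_b) -> float:
    """Geometric-mean ratio exp(mean ln a) / exp(mean ln b).

    MISSING and non-positive values are excluded; NaN when either group is
    empty after exclusion.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a) & (a > 0)]
    b = b[~np.isnan(b) & (b > 0)]
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    return float(np.exp(np.mean(np.log(a)) - np.mean(np.log(b))))


def tukey_kramer(groups: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Tukey-Kramer studentized-range p-value per group pair.

    For groups i, j with means m, sizes n and pooled within-group mean
    square MSW on df error degrees of freedom:

        q_ij = |m_i − m_j| / sqrt(MSW/2 × (1/n_i + 1/n_j))

    referred to the studentized-range distribution with k groups and df
    degrees of freedom.  For balanced groups this reduces to Tukey's HSD.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([np.mean(g) for g in groups])
    df = int(ns.sum() - k)
    if df <= 0:
        return {pair: float("nan") for pair in itertools.combinations(range(k), 2)}
    ssw = sum(float(((g - m) ** 2).sum()) for g, m in zip(groups, means))
    msw = ssw / df
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        if msw <= 0:
            out[(i, j)] = 1.0 if means[i] == means[j] else 0.0
            continue
        se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(means[i] - means[j]) / se
        out[(i, j)] = float(sps.studentized_range.sf(q, k, df))
    return out


@dataclass
class StatResult:
    """Per-feature ANOVA / post-hoc / fold-change summary."""

    feature_id: str
    eligible: bool
    anova_p: float = float("nan")
    anova_p_adjusted: float = float("nan")
    posthoc_p: dict = field(default_factory=dict)   # pair → p
    fc: dict = field(default_factory=dict)          # pair → geometric FC
    not_repeatable: dict = field(default_factory=dict)


def anova_posthoc(pm: PeakMatrix, grouping: pd.Series,
                  log_scale: bool = True,
                  posthoc_alpha: float = P_MAX) -> list[StatResult]:
    """One-way ANOVA + BH FDR + Tukey-Kramer + geometric FC per feature.

    ``grouping`` maps sample_id → condition label (samples not in the
    matrix are ignored).  Intensities are ln-transformed by default,
    consistent with geometric-mean fold changes.  Eligibility requires at
    least three detected replicates per group; BH adjustment spans the
    eligible features of this one comparison.  Features whose values are
    identical across all groups get p = 1 by convention.

    Tukey-Kramer p-values are computed for features whose BH-adjusted
    ANOVA p passes ``posthoc_alpha`` (post-hoc testing follows a
    significant omnibus test; it cannot change the classification of
    features that already fail the ANOVA gate).  Pass ``posthoc_alpha=1``
    to post-hoc every eligible feature.
    """
    grouping = grouping[grouping.index.isin(pm.intensities.columns)]
    labels = sorted(grouping.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    cols = {g: list(grouping.index[grouping == g]) for g in labels}
    pairs = [(a, b) for a, b in itertools.combinations(labels, 2)]

    results: list[StatResult] = []
    vals_of: dict[str, list[np.ndarray]] = {}
    for fid in pm.intensities.index:
        row = pm.intensities.loc[fid]
        groups_raw = [row[cols[g]].dropna() for g in labels]
        groups_raw = [g[g > 0] if log_scale else g for g in groups_raw]
        if any(len(g) < MIN_REPLICATES for g in groups_raw):
            results.append(StatResult(feature_id=str(fid), eligible=False))
            continue
        vals = [np.log(g.to_numpy()) if log_scale else g.to_numpy()
                for g in groups_raw]
        allv = np.concatenate(vals)
        res = StatResult(feature_id=str(fid), eligible=True)
        if np.ptp(allv) == 0:
            res.anova_p = 1.0
            res.posthoc_p = {p: 1.0 for p in pairs}
        else:
            res.anova_p = float(sps.f_oneway(*vals).pvalue)
            if np.isnan(res.anova_p):   # zero within-group variance everywhere
                res.anova_p = 0.0 if any(np.ptp(v) == 0 for v in vals) else 1.0
            vals_of[str(fid)] = vals
        res.fc = {
            (a, b): geometric_fold_change(row[cols[a]], row[cols[b]])
            for a, b in pairs
        }
        results.append(res)

    eligible = [r for r in results if r.eligible]
    if eligible:
        adj = multipletests([r.anova_p for r in eligible], method="fdr_bh")[1]
        for r, p in zip(eligible, adj):
            r.anova_p_adjusted = float(p)
    for r in eligible:
        if not r.posthoc_p and r.anova_p_adjusted <= posthoc_alpha:
            tk = tukey_kramer(vals_of[r.feature_id])
            r.posthoc_p = {(labels[i], labels[j]): p
                           for (i, j), p in tk.items()}
    return results


def classify_not_repeatable(results: list[StatResult]) -> pd.DataFrame:
    """Apply the "not repeatable" rule and summarise per group pair.

    A (feature, pair) is flagged iff adjusted ANOVA p ≤ 0.05, post-hoc
    p ≤ 0.05 and the fold change is > 1.2 or < 1/1.2.  The percentage per
    pair uses the eligible-feature count as denominator.
    """
    pairs = sorted({p for r in results for p in r.fc})
    n_elig = sum(r.eligible for r in results)
    rows = []
    for pair in pairs:
        n_flag = 0
        for r in results:
            if not r.eligible:
                continue
            fc = r.fc.get(pair, float("nan"))
            flagged = (r.anova_p_adjusted <= P_MAX
                       and r.posthoc_p.get(pair, 1.0) <= P_MAX
                       and np.isfinite(fc)
                       and (fc > FC_GATE or fc < 1.0 / FC_GATE))
            r.not_repeatable[pair] = bool(flagged)
            n_flag += flagged
        rows.append({"pair": f"{pair[0]} vs {pair[1]}",
                     "n_eligible": n_elig, "n_flagged": n_flag,
                     "percent_flagged": 100.0 * n_flag / n_elig if n_elig else 0.0})
    return pd.DataFrame(rows)


def welch_edge_centre(pm: PeakMatrix, min_per_zone: int = MIN_REPLICATES
                      ) -> pd.DataFrame:
    """Edge-vs-centre Welch's t-test per plate, BH-adjusted per plate.

    For each plate with ≥ ``min_per_zone`` biological samples in both well
    zones, every feature with enough detected values is tested (Welch
    two-sample t on ln intensities); a feature is flagged iff its BH-adjusted
    p ≤ 0.05 and its geometric fold change passes the 1.2 gate.  Returns one
    summary row per plate.
    """
    out = []
    bio = pm.samples[pm.samples["class"] == "biological"]
    for plate, meta in bio.groupby("plate_id"):
        edge = [s for s in meta.index[meta["well_zone"] == "edge"]
                if s in pm.intensities.columns]
        centre = [s for s in meta.index[meta["well_zone"] == "centre"]
                  if s in pm.intensities.columns]
        if len(edge) < min_per_zone or len(centre) < min_per_zone:
            continue
        pvals, fcs, fids = [], [], []
        for fid in pm.intensities.index:
            a = pm.intensities.loc[fid, edge].dropna()
            b = pm.intensities.loc[fid, centre].dropna()
            a, b = a[a > 0], b[b > 0]
            if len(a) < min_per_zone or len(b) < min_per_zone:
                continue
            la, lb = np.log(a.to_numpy()), np.log(b.to_numpy())
            if np.ptp(np.concatenate([la, lb])) == 0:
                p = 1.0
            else:
                p = float(sps.ttest_ind(la, lb, equal_var=False).pvalue)
                if np.isnan(p):
                    p = 1.0
            pvals.append(p)
            fcs.append(float(np.exp(la.mean() - lb.mean())))
            fids.append(fid)
        if not pvals:
            continue
        adj = multipletests(pvals, method="fdr_bh")[1]
        flagged = [(f, p, fc) for f, p, fc in zip(fids, adj, fcs)
                   if p <= P_MAX and (fc > FC_GATE or fc < 1.0 / FC_GATE)]
        out.append({"plate_id": plate, "n_tested": len(pvals),
                    "n_flagged": len(flagged),
                    "percent_flagged": 100.0 * len(flagged) / len(pvals),
                    "flagged_features": [f for f, _, _ in flagged]})
    return pd.DataFrame(out)


def is_rsd_report(is_intensities: pd.Series, classes: pd.Series) -> pd.DataFrame:
    """RSD (%) of the internal-standard feature per sample class, with n."""
    rows = []
    for cls in ("QC", "biological"):
        ids = classes.index[classes == cls]
        ids = [s for s in ids if s in is_intensities.index]
        if not ids:
            continue
        vals = is_intensities[ids]
        rows.append({"class": cls, "n": int(vals.notna().sum()),
                     "rsd": feature_rsd(vals)})
    return pd.DataFrame(rows)
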