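"""End-to-end orchestration: simulate → screen → drift → process → stats.

:func:`run_pipeline` executes the whole quality-assessment workflow on a
synthetic study (or user-supplied matrix), writes every intermediate report
to the output directory and returns a :class:`RunResult`.  All outputs are
deterministic for a fixed config/seed; the run manifest records the config
snapshot, the stage sequence, the removed-sample ledger and SHA-256 hashes
of every written file (no timestamps, so reruns are byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .core_io import PeakMatrix, read_peak_matrix, write_peak_matrix, \
    write_sample_metadata
from .drift import apply_mz_correction, extract_is_mz_series, fit_drift_spline, \
    verify_drift_with_standards
from .mass import find_internal_standard, strip_is_features
from .pipeline import ProcessResult, process_matrix
from .screen import flag_outlier_samples, is_thresholds, remove_flagged_samples
from .stats import anova_posthoc, classify_not_repeatable, is_rsd_report, mrsd, \
    per_plate_mrsd, welch_edge_centre
from .synthetic import SyntheticStudy, generate_study

log = logging.getLogger("dimsqc")

MRSD_CONTROL_MAX = 30.0   # criterion for biological control samples
MRSD_QC_GUIDE = 20.0      # guidance for intrastudy QCs


@dataclass
class RunResult:
    pm_screened: PeakMatrix
    processed: ProcessResult
    qc_report: dict
    manifest: dict
    screen_report: pd.DataFrame
    drift_report: pd.DataFrame | None = None
    stats_tables: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.6g")


def build_qc_report(res: ProcessResult, is_row: pd.Series,
                    samples: pd.DataFrame) -> dict:
    """Assemble the quality report: stage counts, per-class mRSD at the
    after-PQN / after-RSD-filter checkpoints, per-plate mRSD and IS RSD."""
    checkpoints = {"after_pqn": res.after_pqn, "after_rsd_filter": res.after_rsd}
    classes = samples["class"]
    mrsd_tab = {}
    for label, mat in checkpoints.items():
        entry = {}
        for cls, limit in (("QC", MRSD_QC_GUIDE), ("biological", MRSD_CONTROL_MAX)):
            ids = [s for s in mat.intensities.columns
                   if classes.get(s) == cls]
            if len(ids) < 2:
                continue
            v = mrsd(mat, ids)
            entry[cls] = {"mrsd": round(v, 4), "n": len(ids),
                          "threshold": limit, "passed": bool(v <= limit)}
        mrsd_tab[label] = entry
    plate_tab = per_plate_mrsd(res.after_rsd, checkpoints,
                               mrsd_max=MRSD_CONTROL_MAX)
    surviving = [s for s in res.after_rsd.intensities.columns
                 if s in is_row.index]
    is_tab = is_rsd_report(is_row[surviving], classes[surviving])
    return {
        "feature_counts": res.feature_counts,
        "mrsd": mrsd_tab,
        "per_plate_mrsd": plate_tab.to_dict(orient="records"),
        "is_rsd": is_tab.to_dict(orient="records"),
        "pca_flagged": res.pca_flagged,
    }


def render_qc_report_text(report: dict) -> str:
    """Human-readable rendering of the QC report (stable field order)."""
    lines = ["Quality report", "=============", "", "Spectral feature counts:"]
    for stage, n in report["feature_counts"].items():
        lines.append(f"  {stage:<24s} {n}")
    lines.append("")
    for label, entry in report["mrsd"].items():
        lines.append(f"mRSD (%) {label}:")
        for cls, d in entry.items():
            verdict = "pass" if d["passed"] else "FAIL"
            lines.append(f"  {cls:<12s} {d['mrsd']:.1f}% (n={d['n']}, "
                         f"threshold {d['threshold']:.0f}%: {verdict})")
    lines.append("")
    lines.append("Per-plate mRSD (%):")
    for row in report["per_plate_mrsd"]:
        verdict = "pass" if row["passed"] else "FAIL"
        lines.append(f"  {row['plate_id']:<8s} {row['checkpoint']:<18s} "
                     f"{row['mrsd']:.1f}% ({verdict})")
    lines.append("")
    lines.append("Internal-standard RSD (%):")
    for row in report["is_rsd"]:
        lines.append(f"  {row['class']:<12s} {row['rsd']:.1f}% (n={row['n']})")
    if report.get("pca_flagged"):
        lines.append("")
        lines.append(f"PCA-flagged samples: {', '.join(report['pca_flagged'])}")
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: RunConfig, outdir: str | Path,
                 study: SyntheticStudy | None = None) -> RunResult:
    """Run the full workflow and write all outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    removed_ledger: list[dict] = []

    # ---- input -----------------------------------------------------------
    observed_mz = None
    truth = None
    if study is None:
        if cfg.matrix_path:
            pm = read_peak_matrix(cfg.matrix_path, cfg.sample_meta_path)
        else:
            study = generate_study(cfg.study)
    if study is not None:
        pm = study.pm
        observed_mz = study.observed_mz
        truth = study.truth
        write_peak_matrix(pm, outdir / "matrix_input.tsv")
        write_sample_metadata(pm.samples, outdir / "samples.tsv")
    log.info("input: %d features × %d samples", pm.n_features, pm.n_samples)

    # ---- IS-based sample screening --------------------------------------
    is_cfg = cfg.internal_standard
    is_feature = find_internal_standard(pm, is_cfg)
    thresholds = is_thresholds(pm.intensities.loc[is_feature],
                               pm.samples["class"], k_qc=is_cfg.k_qc,
                               k_study=is_cfg.k_study)
    screen_report = flag_outlier_samples(pm, is_feature, thresholds)
    pm, flagged = remove_flagged_samples(pm, screen_report)
    for sid in flagged:
        removed_ledger.append({"sample_id": sid, "stage": "is_screen",
                               "reason": "IS intensity outside median±k·MAD"})
    _write_tsv(screen_report, outdir / "screen_report.tsv")
    log.info("screening: %d sample(s) removed", len(flagged))

    # ---- m/z drift correction (HT mode) ---------------------------------
    drift_report = None
    if cfg.mode == "ht" and observed_mz is not None:
        keep = pm.intensities.columns
        series = extract_is_mz_series(observed_mz.loc[is_feature, keep],
                                      is_cfg.expected_mz,
                                      pm.samples["acquisition_order"])
        model = fit_drift_spline(series)
        drift_report = series.assign(fitted=model.predict(series["order"]))
        _write_tsv(drift_report, outdir / "mz_drift.tsv")
        observed_mz = apply_mz_correction(
            observed_mz[keep], pm.samples["acquisition_order"].to_numpy(), model)
        if truth is not None and truth.standards_features:
            std = {}
            for sid_f in truth.standards_features:
                ref = float(pm.mz.get(sid_f, np.nan))
                if np.isnan(ref):
                    continue
                ser = extract_is_mz_series(study.observed_mz.loc[sid_f, keep],
                                           ref, pm.samples["acquisition_order"])
                std[sid_f] = ser
            ver = verify_drift_with_standards(std, model,
                                              r_threshold=cfg.drift_r_threshold)
            _write_tsv(ver, outdir / "drift_verification.tsv")

    # ---- strip the IS family, keep its intensities for reporting --------
    pm_stats, is_rows = strip_is_features(pm, is_feature,
                                          ppm_tol=is_cfg.ppm_tol,
                                          polarity=is_cfg.polarity)
    is_row = pm.intensities.loc[is_feature]

    # ---- matrix cascade --------------------------------------------------
    processed = process_matrix(pm_stats, cfg.pipeline)
    for sid in processed.pca_flagged:
        removed_ledger.append({"sample_id": sid, "stage": "pca_outlier_pass",
                               "reason": "Hotelling T2 above confidence bound"})
    write_peak_matrix(processed.after_rsd, outdir / "matrix_processed.tsv")
    if processed.multivariate is not None:
        write_peak_matrix(processed.multivariate, outdir / "matrix_multivariate.tsv")

    # ---- statistics ------------------------------------------------------
    stats_tables: dict[str, pd.DataFrame] = {}
    bio = processed.after_rsd.samples
    bio_ids = bio.index[bio["class"] == "biological"]
    plates = bio.loc[bio_ids, "plate_id"]
    if plates.nunique() >= 2 and (plates.value_counts() >= 3).all():
        results = anova_posthoc(processed.after_rsd, plates)
        stats_tables["plate_comparison"] = classify_not_repeatable(results)
        _write_tsv(stats_tables["plate_comparison"],
                   outdir / "plate_comparison.tsv")
    ec = welch_edge_centre(processed.after_rsd)
    if len(ec):
        stats_tables["edge_centre"] = ec.drop(columns=["flagged_features"])
        _write_tsv(stats_tables["edge_centre"], outdir / "edge_centre.tsv")

    # ---- report + manifest ----------------------------------------------
    qc_report = build_qc_report(processed, is_row, pm.samples)
    (outdir / "qc_report.json").write_text(
        json.dumps(qc_report, indent=2, sort_keys=True) + "\n")
    (outdir / "qc_report.txt").write_text(render_qc_report_text(qc_report))

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "config": cfg.snapshot(),
        "stages": processed.stages,
        "is_feature": is_feature,
        "removed_samples": removed_ledger,
        "files": {},
    }
    for p in sorted(outdir.glob("*.tsv")) + [outdir / "qc_report.json"]:
        manifest["files"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")

    return RunResult(pm_screened=pm, processed=processed, qc_report=qc_report,
                     manifest=manifest, screen_report=screen_report,
                     drift_report=drift_report, stats_tables=stats_tables)
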