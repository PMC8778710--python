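"""Synthetic direct-infusion MS studies with known ground truth.

The generator emulates the structure a plate-based DIMS metabolomics QC
pipeline has to cope with: feature-wise log-normal intensities with separate
analytical and biological variance components, plate/batch structure, pooled
intrastudy QCs and extraction blanks, a spiked internal-standard feature,
smooth m/z drift over acquisition order, multiplicative intensity drift per
batch, failed-infusion outlier samples, intensity-dependent missingness,
per-sample dilution and (optionally) planted differential features.

The model is multiplicative:

    intensity(f, s) = exp(base_f + plate_{f,p(s)} + bio_{f,s} + eps_{f,s})
                      × dilution_s × drift(order_s) × fail_s

with ``bio`` shared across all QC samples (they are aliquots of one pool),
absent for the internal standard and the spiked standards mixture, and
``fail_s`` = ``failed_infusion_factor`` for failed infusions, else 1.
Values below the detection threshold become MISSING with a configurable
probability (thresholded-at-random missingness).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import PeakMatrix, derive_well_zone

__all__ = ["StudyConfig", "SyntheticTruth", "SyntheticStudy", "generate_study",
           "generate_scan_sets", "ScanSet"]

_ROWS = string.ascii_uppercase[:8]
WELL_LABELS = [f"{r}{c}" for r in _ROWS for c in range(1, 13)]

#: [M+H]+ of L-tryptophan-d5 (the polar-assay internal standard).
TRP_D5_MH = 210.12297


@dataclass
class StudyConfig:
    """Parameters of a synthetic study.

    Defaults describe a desk-scale workflow-assessment study: a few 96-well
    plates of biological control samples, pooled intrastudy QCs infused after
    every eight study samples, extraction blanks, ~10% analytical RSD and
    ~20% biological RSD on the log scale.
    """

    n_features: int = 300
    mz_range: tuple[float, float] = (70.0, 700.0)
    n_plates: int = 3
    wells_per_plate: int = 30
    n_qc: int = 14
    n_blank: int = 4
    n_groups: int = 1                 # biological condition groups (balanced)
    n_batches: int = 1                # acquisition batches (HT mode > 1)
    sigma_analytical: float = 0.10    # log-scale SD, analytical replication
    sigma_biological: float = 0.20    # log-scale SD, biological replication
    plate_effect_sd: float = 0.05     # log-scale SD of per-(feature, plate) shifts
    base_log_mean: float = 11.5       # mean of per-feature baseline ln-intensity
    base_log_sd: float = 1.2
    detection_threshold: float = 2.0e3
    p_missing_below_threshold: float = 1.0
    mz_drift_shape: str = "linear"    # none | linear | quadratic | sinusoidal
    mz_drift_amplitude: float = 3.0   # ppm over the run
    mz_noise_ppm: float = 0.3         # per-(feature, sample) m/z measurement noise
    intensity_drift_amplitude: float = 0.0  # fractional decay across each batch
    p_failed_infusion: float = 0.0
    failed_infusion_factor: float = 0.01
    n_planted_diff: int = 0
    planted_log_fc: float = float(np.log(2.0))
    dilution_log_sd: float = 0.10     # per-sample dilution ~ LogNormal(0, sd)
    dilution_factors: dict | None = None  # explicit per-sample override
    is_mz: float = TRP_D5_MH
    is_level: float = 5.0e6           # internal-standard intensity scale
    is_isotope: bool = True           # plant the IS +1 isotopologue feature
    n_standards: int = 5              # spiked standards-mixture features
    blank_feature_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_diff > self.n_features:
            raise ValueError("n_planted_diff exceeds n_features")
        if self.n_planted_diff > 0 and self.n_groups < 2:
            raise ValueError("planted differential features need n_groups >= 2")
        for name in ("sigma_analytical", "sigma_biological", "plate_effect_sd",
                     "dilution_log_sd", "mz_noise_ppm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_missing_below_threshold", "p_failed_infusion"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mz_drift_shape not in ("none", "linear", "quadratic", "sinusoidal"):
            raise ValueError(f"unknown mz_drift_shape: {self.mz_drift_shape}")
        if self.wells_per_plate > 96:
            raise ValueError("wells_per_plate cannot exceed 96")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study (everything tests need to verify)."""

    base_log_intensity: pd.Series
    planted_features: list[str]
    planted_log_fc: float
    group_of_sample: pd.Series
    failed_samples: list[str]
    mz_drift_ppm: pd.Series          # per sample, indexed by sample_id
    intensity_drift: pd.Series       # per sample multiplicative factor
    dilution: pd.Series
    blank_origin_features: list[str]
    is_feature: str
    is_isotope_feature: str | None
    standards_features: list[str]
    config: StudyConfig = field(repr=False, default=None)


@dataclass
class SyntheticStudy:
    """A generated study: matrix, metadata, per-sample m/z and truth."""

    pm: PeakMatrix
    samples: pd.DataFrame
    observed_mz: pd.DataFrame        # features × samples observed m/z (Da)
    truth: SyntheticTruth


def _drift_ppm(shape: str, amplitude: float, t: np.ndarray) -> np.ndarray:
    if shape == "none" or amplitude == 0:
        return np.zeros_like(t)
    if shape == "linear":
        return amplitude * t
    if shape == "quadratic":
        return amplitude * t**2
    if shape == "sinusoidal":
        return amplitude * np.sin(2 * np.pi * t)
    raise ValueError(shape)


def _build_layout(cfg: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample table: classes, plates, wells, groups and acquisition schedule.

    Intrastudy QCs are interleaved after every eight study samples, with
    half the blanks at the start of the run and half at the end.
    """
    rows = []
    for p in range(cfg.n_plates):
        plate = f"TP{p + 1}"
        for w in range(cfg.wells_per_plate):
            rows.append({
                "sample_id": f"{plate}_{WELL_LABELS[w]}",
                "class": "biological",
                "plate_id": plate,
                "well": WELL_LABELS[w],
                "group": f"G{(w % cfg.n_groups) + 1}",
            })
    for q in range(cfg.n_qc):
        rows.append({
            "sample_id": f"QC{q + 1:02d}",
            "class": "QC",
            "plate_id": "QCP",
            "well": WELL_LABELS[q % 96],
            "group": "QC",
        })
    for b in range(cfg.n_blank):
        rows.append({
            "sample_id": f"BL{b + 1:02d}",
            "class": "blank",
            "plate_id": "QCP",
            "well": WELL_LABELS[(cfg.n_qc + b) % 96],
            "group": "blank",
        })
    df = pd.DataFrame(rows)

    bio_ids = list(df.loc[df["class"] == "biological", "sample_id"])
    qc_ids = list(df.loc[df["class"] == "QC", "sample_id"])
    bl_ids = list(df.loc[df["class"] == "blank", "sample_id"])
    lead = bl_ids[: max(1, len(bl_ids) // 2)] if bl_ids else []
    tail = [b for b in bl_ids if b not in lead]
    schedule = list(lead)
    qc_iter = iter(qc_ids)
    for i, sid in enumerate(bio_ids):
        schedule.append(sid)
        if (i + 1) % 8 == 0:
            nxt = next(qc_iter, None)
            if nxt is not None:
                schedule.append(nxt)
    schedule.extend(qc_iter)  # leftover QCs at the end of the run
    schedule.extend(tail)
    order = {sid: i + 1 for i, sid in enumerate(schedule)}
    df["acquisition_order"] = df["sample_id"].map(order)

    n = len(df)
    batch_size = int(np.ceil(n / cfg.n_batches))
    df["batch_id"] = "B" + (1 + (df["acquisition_order"] - 1) // batch_size).astype(str)
    df["well_zone"] = df["well"].map(derive_well_zone)
    plate_num = df["plate_id"].str.extract(r"(\d+)", expand=False).fillna("0").astype(int)
    df["extraction_day"] = np.where(df["class"] == "biological",
                                    1 + (plate_num - 1) // 2, 1)
    df["plate_extraction_order"] = np.where(df["class"] == "biological", plate_num, 0)
    df["deck_position"] = np.where(plate_num % 2 == 1, "a", "b")
    return df


def generate_study(cfg: StudyConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from a single seed.

    All randomness flows from ``cfg.seed`` through one generator; a fixed
    config reproduces the study exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    samples = _build_layout(cfg, rng)
    n_s = len(samples)
    sample_ids = list(samples["sample_id"])
    is_blank = (samples["class"] == "blank").to_numpy()
    is_qc = (samples["class"] == "QC").to_numpy()

    # --- feature panel: regular features + standards + IS (+ isotope) -----
    feat_ids = [f"F{i + 1:04d}" for i in range(cfg.n_features)]
    mz = np.sort(rng.uniform(*cfg.mz_range, size=cfg.n_features))
    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_features)

    std_idx = (np.linspace(0, cfg.n_features - 1, cfg.n_standards).round().astype(int)
               if cfg.n_standards else np.array([], dtype=int))
    standards = [feat_ids[i] for i in std_idx]
    base[std_idx] = np.log(cfg.is_level / 2)  # spiked well above detection

    n_blank_feat = int(round(cfg.blank_feature_fraction * cfg.n_features))
    blank_candidates = [i for i in range(cfg.n_features) if i not in set(std_idx)]
    blank_idx = rng.choice(blank_candidates, size=min(n_blank_feat, len(blank_candidates)),
                           replace=False)
    blank_origin = sorted(feat_ids[i] for i in blank_idx)

    planted_candidates = [i for i in range(cfg.n_features)
                          if i not in set(std_idx) and i not in set(blank_idx)]
    planted_idx = np.array(sorted(planted_candidates[: cfg.n_planted_diff]), dtype=int)
    planted = [feat_ids[i] for i in planted_idx]

    # --- per-sample structure --------------------------------------------
    t = (samples["acquisition_order"].to_numpy() - 1) / max(n_s - 1, 1)
    drift_ppm = _drift_ppm(cfg.mz_drift_shape, cfg.mz_drift_amplitude, t)

    frac_in_batch = samples.groupby("batch_id")["acquisition_order"].rank(method="first")
    sizes = samples.groupby("batch_id")["acquisition_order"].transform("size")
    int_drift = 1.0 - cfg.intensity_drift_amplitude * (
        (frac_in_batch - 1) / np.maximum(sizes - 1, 1)
    ).to_numpy()

    if cfg.dilution_factors is not None:
        dilution = np.array([cfg.dilution_factors.get(s, 1.0) for s in sample_ids])
    else:
        dilution = np.exp(rng.normal(0.0, cfg.dilution_log_sd, size=n_s))
    dilution[is_blank] = 1.0

    failed = (rng.random(n_s) < cfg.p_failed_infusion) & ~is_blank
    fail_factor = np.where(failed, cfg.failed_infusion_factor, 1.0)

    # --- intensity matrix -------------------------------------------------
    plate_ids = sorted(samples["plate_id"].unique())
    plate_eff = {p: rng.normal(0, cfg.plate_effect_sd, size=cfg.n_features)
                 for p in plate_ids}
    plate_eff["QCP"] = np.zeros(cfg.n_features)

    bio_pool = rng.normal(0, cfg.sigma_biological, size=cfg.n_features)
    log_int = np.empty((cfg.n_features, n_s))
    for j, (_, row) in enumerate(samples.iterrows()):
        if row["class"] == "QC":
            bio = bio_pool
        elif row["class"] == "blank":
            bio = np.zeros(cfg.n_features)
        else:
            bio = rng.normal(0, cfg.sigma_biological, size=cfg.n_features)
        eps = rng.normal(0, cfg.sigma_analytical, size=cfg.n_features)
        log_int[:, j] = base + plate_eff[row["plate_id"]] + bio + eps

    # spiked standards: constant level + analytical noise only
    if len(std_idx):
        eps_std = rng.normal(0, cfg.sigma_analytical, size=(len(std_idx), n_s))
        log_int[std_idx, :] = np.log(cfg.is_level / 2) + eps_std

    # planted condition effects
    if len(planted_idx):
        in_alt = samples["group"].isin(
            [f"G{g}" for g in range(2, cfg.n_groups + 1)]).to_numpy()
        log_int[np.ix_(planted_idx, np.where(in_alt)[0])] += cfg.planted_log_fc

    intensity = np.exp(log_int) * dilution[None, :] * int_drift[None, :] \
        * fail_factor[None, :]

    # blanks carry only blank-origin features (plus the IS, added below)
    blank_cols = np.where(is_blank)[0]
    keep_in_blank = np.zeros(cfg.n_features, dtype=bool)
    keep_in_blank[blank_idx] = True
    for j in blank_cols:
        intensity[~keep_in_blank, j] = np.nan
        # contaminant level comparable to sample level, no dilution/biology
        eps_b = rng.normal(0, cfg.sigma_analytical, size=len(blank_idx))
        intensity[blank_idx, j] = np.exp(base[blank_idx] + eps_b) * int_drift[j]

    # --- internal standard (+ isotopologue) -------------------------------
    eps_is = rng.normal(0, cfg.sigma_analytical, size=n_s)
    is_int = cfg.is_level * np.exp(eps_is) * int_drift * fail_factor
    rows = [intensity, is_int[None, :]]
    feat_ids_all = feat_ids + ["IS"]
    mz_all = np.append(mz, cfg.is_mz)
    base_all = np.append(base, np.log(cfg.is_level))
    iso_id = None
    if cfg.is_isotope:
        iso_id = "IS_M1"
        rows.append((0.25 * is_int)[None, :])
        feat_ids_all = feat_ids_all + [iso_id]
        mz_all = np.append(mz_all, cfg.is_mz + 1.00336)
        base_all = np.append(base_all, np.log(0.25 * cfg.is_level))
    intensity = np.vstack(rows)

    # --- thresholded-at-random missingness --------------------------------
    below = intensity < cfg.detection_threshold
    knock = below & (rng.random(intensity.shape) < cfg.p_missing_below_threshold)
    intensity = np.where(knock, np.nan, intensity)

    # --- observed m/z per (feature, sample) -------------------------------
    mz_noise = rng.normal(0, cfg.mz_noise_ppm, size=(len(feat_ids_all), n_s))
    observed_mz = mz_all[:, None] * (1.0 + (drift_ppm[None, :] + mz_noise) / 1e6)
    observed_mz = pd.DataFrame(observed_mz, index=feat_ids_all, columns=sample_ids)
    rep_mz = observed_mz.median(axis=1)

    pm = PeakMatrix(
        intensities=pd.DataFrame(intensity, index=feat_ids_all, columns=sample_ids),
        mz=rep_mz,
        samples=samples,
    )
    order = pm.samples.index  # canonical (acquisition) order
    idx = {s: i for i, s in enumerate(sample_ids)}
    as_series = lambda v: pd.Series([v[idx[s]] for s in order], index=order)

    truth = SyntheticTruth(
        base_log_intensity=pd.Series(base_all, index=feat_ids_all),
        planted_features=planted,
        planted_log_fc=cfg.planted_log_fc,
        group_of_sample=pm.samples["group"].copy(),
        failed_samples=[s for s in order if failed[idx[s]]],
        mz_drift_ppm=as_series(drift_ppm),
        intensity_drift=as_series(int_drift),
        dilution=as_series(dilution),
        blank_origin_features=blank_origin,
        is_feature="IS",
        is_isotope_feature=iso_id,
        standards_features=standards,
        config=cfg,
    )
    return SyntheticStudy(pm=pm, samples=pm.samples, observed_mz=observed_mz[order],
                          truth=truth)


# ---------------------------------------------------------------------------
# replicate-scan peak lists (for the scan-processing stage)
# ---------------------------------------------------------------------------

@dataclass
class ScanSet:
    """Replicate-scan peak lists for a set of samples plus their truth."""

    peaks: pd.DataFrame              # sample_id, window_id, scan_index, mz, intensity
    windows: pd.DataFrame            # window_id, mz_lo, mz_hi
    true_features: pd.DataFrame      # feature_id, mz, intensity


def generate_scan_sets(cfg: StudyConfig, n_windows: int = 5,
                       n_replicate_scans: int = 3, dropout_prob: float = 0.0,
                       n_samples: int = 3, overlap_fraction: float = 0.10,
                       scan_mz_noise_ppm: float = 1.0,
                       scan_int_sd: float = 0.05) -> ScanSet:
    """Simulate per-sample replicate-scan peak lists over stitched m/z windows.

    Each true feature appears in each replicate scan with probability
    ``1 - dropout_prob``, with per-scan m/z jitter and log-normal intensity
    noise.  Adjacent SIM windows overlap by ``overlap_fraction`` of their
    width, so features near a boundary are recorded in both windows (the
    stitching stage must deduplicate them).
    """
    if n_replicate_scans < 1:
        raise ValueError("need at least one replicate scan")
    if not 0 <= dropout_prob <= 1:
        raise ValueError("dropout_prob must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed + 1)

    lo, hi = cfg.mz_range
    step = (hi - lo) / n_windows
    pad = overlap_fraction * step / 2
    windows = pd.DataFrame({
        "window_id": range(n_windows),
        "mz_lo": [max(lo, lo + i * step - pad) for i in range(n_windows)],
        "mz_hi": [min(hi, lo + (i + 1) * step + pad) for i in range(n_windows)],
    })

    mz = np.sort(rng.uniform(lo, hi, size=cfg.n_features))
    level = np.exp(rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_features))
    true_features = pd.DataFrame({
        "feature_id": [f"F{i + 1:04d}" for i in range(cfg.n_features)],
        "mz": mz, "intensity": level,
    })

    recs = []
    for s in range(n_samples):
        sid = f"S{s + 1:02d}"
        for _, w in windows.iterrows():
            in_w = (mz >= w.mz_lo) & (mz <= w.mz_hi)
            for scan in range(1, n_replicate_scans + 1):
                present = in_w & (rng.random(cfg.n_features) >= dropout_prob)
                jitter = rng.normal(0, scan_mz_noise_ppm, size=cfg.n_features)
                obs_mz = mz * (1 + jitter / 1e6)
                obs_int = level * np.exp(rng.normal(0, scan_int_sd, size=cfg.n_features))
                for i in np.where(present)[0]:
                    recs.append((sid, int(w.window_id), scan, obs_mz[i], obs_int[i]))
    peaks = pd.DataFrame(recs, columns=["sample_id", "window_id", "scan_index",
                                        "mz", "intensity"])
    return ScanSet(peaks=peaks, windows=windows, true_features=true_features)
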