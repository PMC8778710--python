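# dimsqc

Quality assessment and post-acquisition processing for **plate-based,
direct-infusion mass-spectrometry (DIMS) metabolomics**.

High-throughput in vitro metabolomics extracts metabolites from 96-well
microplates on a robotic platform and infuses each well by nanoelectrospray
DIMS. Before any biology can be read out of such data, the peak matrix has
to survive a battery of quality controls: failed infusions must be caught,
mass-accuracy and signal drift corrected, contaminant and irreproducible
features removed, dilution normalised, and the repeatability of the whole
extraction workflow quantified. `dimsqc` implements that processing and
assessment cascade as a tested Python library with a CLI, together with a
synthetic-study generator that produces complete studies with known ground
truth (plate layout, pooled intrastudy QCs, extraction blanks, spiked
internal standard, drift, failed infusions, planted fold changes), so every
stage is verifiable without access to instrument data.

## What it computes

For a features × samples intensity matrix with explicit missingness
(`PeakMatrix`), sample classes {blank, QC, biological} and acquisition
order:

* **Internal-standard screening** — the IS is located by accurate mass
  (±5 ppm on [M+H]⁺/[M−H]⁻) and every sample is screened against
  class-specific robust bounds
  `median(IS) ± k · 1.4826 · MAD(IS)` (k = 3 for intrastudy QCs, k = 2 for
  study samples; k = 3 everywhere in high-throughput mode). A missing IS
  counts as a recorded zero in the median/MAD — a sample without IS is
  itself evidence of a failed infusion. Flagged samples are removed and
  the workflow rerun.
* **m/z drift correction** — a cubic smoothing spline fitted to the IS
  ppm-error series over acquisition order, smoothing selected by explicit
  leave-one-out cross-validation over a log-spaced grid; every sample's
  m/z values are divided by `1 + ppm/1e6`. A spiked standards mixture
  verifies the drift is mass-wide (Pearson r per standard).
* **Filter cascade** — blank subtraction (fold-over-blank), presence
  filter over all samples (≥80%, HT ≥50%), sparse-sample removal
  (>30% missing; HT >40/50% by assay), QC-presence filter (≥70%),
  probabilistic quotient normalisation against the QC median spectrum,
  QC-anchored signal-drift correction (HT mode, per feature and batch),
  and a QC-RSD filter (>30% removed). The multivariate branch adds kNN
  imputation (k = 5), generalised-log transform (λ ML-optimised on QCs),
  mean centring and a Hotelling-T² PCA outlier pass at 95% confidence
  with one rerun.
* **Repeatability statistics** — per-feature RSD and median RSD (mRSD)
  per class and per plate (30% criterion for biological controls, 20%
  guidance for QCs); one-way ANOVA on ln intensities with
  Benjamini-Hochberg FDR, Tukey-Kramer post-hoc tests and geometric-mean
  fold changes; a feature is **"not repeatable"** for a comparison iff
  adjusted p ≤ 0.05, post-hoc p ≤ 0.05 and FC > 1.2 or < 1/1.2, with
  eligibility requiring ≥3 detected replicates per group; Welch's t-test
  for edge-vs-centre well effects per plate.

A simplified scan-processing stage (replicate-scan filtering at ≥2 scans
and ≥0.6 of 3 replicates, SIM-window stitching, ppm-tolerance alignment)
turns per-sample replicate-scan peak lists into an aligned matrix.

## Worked example

Run the whole workflow on a simulated study (3 plates of control samples,
14 pooled QCs, 4 extraction blanks, ~300 features):

```bash
dimsqc all --seed 3 --out run/
cat run/qc_report.txt
```

```
Quality report
=============

Spectral feature counts:
  blank_subtract           270
  presence_filter_all      268
  ...
  rsd_filter               268

mRSD (%) after_pqn:
  QC           9.5% (n=12, threshold 20%: pass)
  biological   22.6% (n=87, threshold 30%: pass)

Per-plate mRSD (%):
  TP1      after_pqn          22.0% (pass)
  TP2      after_pqn          21.7% (pass)
  TP3      after_pqn          22.4% (pass)

Internal-standard RSD (%):
  QC           4.9% (n=12)
  biological   8.8% (n=87)

PCA-flagged samples: TP1_C2
```

Reading it: 302 simulated features enter; blank subtraction removes the
~30 contaminant (blank-origin) features and the IS family is set aside,
leaving 270; the presence filters barely bite because the study is dense.
QC mRSD ≈ 10% is the purely analytical repeatability (the generator's
σ_analytical = 0.1 on the log scale corresponds to ≈10% RSD); biological
mRSD ≈ 23% adds the biological variance component and passes the 30%
criterion. The IS RSD is tighter than the all-feature mRSD because the IS
carries no biological or dilution variation. One sample is flagged by the
PCA pass and the cascade is rerun without it.

Every subcommand (`simulate`, `process-scans`, `screen`, `drift`,
`process`, `stats`, `report`) runs one stage in isolation; `--mode ht`
switches to the high-throughput thresholds and enables both drift
corrections. A YAML config controls every threshold; unknown keys are
startup errors. The run manifest (`manifest.json`) records the config
snapshot, stage sequence, removed samples and SHA-256 of every output, and
contains no timestamps — identical seeds give byte-identical runs.

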