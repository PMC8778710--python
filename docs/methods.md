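# Methods

## The data and its quality problem

A plate-based DIMS metabolomics study yields, after scan processing and
alignment, a features × samples matrix of peak intensities in which a cell
is either a non-negative measurement or MISSING (not detected/aligned —
encoded as an empty cell on disk and NaN in memory; a recorded zero is a
value, not MISSING). Samples belong to three classes: **extraction
blanks** (no-cell wells, processed identically), **intrastudy QCs**
(aliquots of one pooled extract re-infused through the run, measuring
purely analytical variation) and **biological** samples. Each sample
carries its plate, well (hence edge/centre zone), batch, acquisition order,
extraction day/order and deck position. Every stage of `dimsqc` transforms
this object and logs (features_in/out, samples_in/out).

## Internal-standard screening

The isotopically labelled internal standard (default: L-tryptophan-d₅,
[M+H]⁺ at m/z 210.12297) is spiked into the extraction solvent, so it must
appear in every infused sample at a similar intensity. The IS feature is
located in the aligned matrix as the feature within ±5 ppm of the expected
adduct m/z with the highest median intensity over non-blank samples (the
IS is spiked at µM level and should dominate; ties break to the smallest
|ppm error|). Screening bounds per class are

    median(IS) ± k × 1.4826 × MAD(IS)

with k = 3 for QCs and k = 2 for study samples in workflow-assessment
mode, and k = 3 for both in high-throughput mode. The factor 1.4826 makes
the MAD a consistent SD estimate under normality. MISSING IS values enter
the median and MAD as zeros — for this feature only — because an
undetected IS is itself the failure signature. Blanks are never screened.
After removal the downstream stages are recomputed once; further cycles
are opt-in.

A consequence worth knowing: for Gaussian-like noise the ±2·(1.4826·MAD)
band excludes ≈4.6% of perfectly healthy samples whatever the noise scale,
so the k = 2 study-sample rule trades a few percent of false removals for
certain capture of gross failures (a failed infusion at ~1% of the normal
IS intensity is dozens of robust SDs below the band). k is config-exposed.

## m/z drift

Mass accuracy can drift over a multi-day run. The IS provides one signed
ppm error per sample against its known m/z; a cubic smoothing spline is
fitted to (acquisition order, ppm error) with the smoothing parameter λ
chosen by *explicit leave-one-out cross-validation* over a 12-point
log-spaced grid (1e−3 … 1e8, near-interpolation to near-linear): for each
candidate the model is refitted n times on n−1 points and the mean squared
prediction error minimised. Correction is multiplicative and per sample —
`mz / (1 + ppm̂(order)/1e6)` — applied before cross-sample alignment, and
exactly invertible given the model. Orders outside the fitted range are
predicted by constant extrapolation from the nearest endpoint, with a
warning. Fitting needs ≥10 usable points and ≥4 distinct orders. A spiked
standards mixture spanning the m/z range guards against over-trusting a
single feature: each standard's ppm series is correlated with the model's
prediction (pass at Pearson r ≥ 0.7 by default; a single standard marks
the verification "partial", none marks it "not verified").

## Filter cascade

Assessment-mode order, each threshold config-exposed with these defaults:

1. **Blank subtraction** — keep a feature iff mean over non-blank samples
   ≥ 10 × mean over blanks (features never seen in a blank always
   survive); drop blank columns. The fold and mean-vs-median statistic are
   config choices; fold-over-blank is the conventional reading of "blank
   subtraction" for DIMS peak matrices.
2. **Presence filter** — feature present (non-MISSING) in ≥80% of all
   samples (50% in HT mode). "At least" → `≥`.
3. **Sparse samples** — drop samples with missing fraction strictly
   exceeding 30% ("exceeding" → `>`; HT: 40% polar positive, 50% other
   assays).
4. **QC presence** — feature present in ≥70% of intrastudy QCs.
5. **Signal-drift correction** (HT mode only) — per feature and batch, a
   smoothing spline (same LOOCV machinery, 4-point λ grid, fitted on log
   intensities) through the QC intensities vs order; all samples divided
   by the curve and rescaled to the batch QC median. Batches with <4 QCs,
   or features where fitting fails, fall back to batch-median scaling
   against the overall QC median. Placed *before* PQN, matching the
   order in which a corrected dataset is subsequently normalised.
6. **PQN** — reference = per-feature median over QCs (the designated
   reference material; switchable to the all-sample median); each sample
   divided by the median of its quotients against the reference over
   co-present features with positive reference. Needs ≥3 QCs.
7. **QC-RSD filter** — remove features with RSD (SD/mean × 100 over
   non-MISSING QC values) above 30%; features with <2 QC values cannot
   demonstrate repeatability and are removed.

The metrics/statistics branch uses the un-imputed post-RSD matrix. The
multivariate branch continues: **kNN imputation** (k = 5; sample-sample
Euclidean distances over co-present features on the standardised matrix,
imputed value = mean of the feature over the k nearest samples that
measured it — deterministic), **glog** `ln((x+√(x²+λ))/2)` with λ
maximised by profile likelihood on QC replicates (per-feature-mean,
common-variance Gaussian model with the transform Jacobian; bounded
search on log₁₀λ; fixed fallback), **mean centring**, and a **PCA
outlier pass**: Hotelling's T² on the first two components against
`2(n−1)/(n−2)·F₀.₉₅(2, n−2)`. Because pooled QCs share one biological
draw, they form a tight cluster offset from the biological samples; T² is
therefore evaluated *within each sample class*, so that the smaller class
is not flagged wholesale. Flagged samples trigger exactly one rerun of
the cascade from blank subtraction.

## Repeatability statistics

mRSD = median over features of the per-feature RSD within a sample class,
reported per plate and at the after-PQN and after-RSD-filter checkpoints,
with a 30% criterion for biological controls and 20% guidance for QCs.
Condition comparisons: one-way ANOVA per feature on ln intensities
(consistent with multiplicative error and geometric-mean fold changes;
raw-scale switchable), BH FDR across the eligible features of one
comparison, Tukey-Kramer studentized-range post-hoc p-values with the
harmonic-mean correction for unbalanced groups (reducing exactly to Tukey
HSD when balanced), and geometric-mean fold changes
`exp(mean ln A − mean ln B)` with non-positive values excluded. A
(feature, pair) is **not repeatable** iff adjusted ANOVA p ≤ 0.05 AND
post-hoc p ≤ 0.05 AND FC > 1.2 or < 1/1.2 — "absolute fold change above
1.2" is read symmetrically in ratio space. Eligibility (≥3 detected
replicates per group) is evaluated on un-imputed values. Post-hoc tests
are computed for features passing the adjusted-p gate (they cannot change
the classification of features that already fail it; `posthoc_alpha=1`
forces post-hoc everywhere). Degenerate inputs: all values identical →
p = 1 by convention; zero within-group variance with distinct means →
p = 0. Edge-vs-centre effects use Welch's t-test per plate (both zones
≥3 samples), BH per plate, with the same FC gate.

## The synthetic generator

`generate_study` emulates the structure the pipeline must handle, from a
single seed through one RNG (fixed seed → byte-identical studies):

* log-normal intensities, `exp(base_f + plate_{f,p} + bio_{f,s} + ε_{f,s})
  × dilution_s × drift(order_s) × fail_s`, with σ_analytical = 0.10 and
  σ_biological = 0.20 (log scale) by default — giving ≈10% analytical RSD
  (QC mRSD) and ≈20–25% total RSD in controls, the regime a well-behaved
  automated workflow operates in — and per-(feature, plate) effects of
  SD 0.05;
* pooled QCs sharing one biological draw (they measure analytical
  variation only), blanks carrying only contaminant ("blank-origin",
  10% of features) peaks plus the IS, QCs interleaved after every eight
  study samples, blanks split between run start and end;
* an IS feature (plus its +1 isotopologue at +1.00336 Da) with analytical
  noise only — no biology, no dilution — and a 5-feature standards
  mixture spread across the m/z range;
* smooth m/z drift over acquisition order (none/linear/quadratic/
  sinusoidal, default linear 3 ppm — within the annotation tolerance, as
  observed drifts are) plus 0.3 ppm per-measurement m/z noise; optional
  per-batch multiplicative intensity decay;
* failed infusions (probability 0 by default; factor 0.01) multiplying a
  whole sample; per-sample dilution ~ LogNormal(0, 0.1); values below the
  detection threshold (2×10³) become MISSING (thresholded-at-random, the
  simplest mechanism consistent with presence filters);
* optionally, planted differential features with a known log fold change
  between balanced groups.

The truth object records everything needed to verify downstream stages.
`generate_scan_sets` additionally simulates replicate-scan peak lists over
overlapping SIM windows with per-scan dropout, m/z jitter and intensity
noise.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: ion suppression and matrix effects,
isotope patterns and correlated adduct features, structured (non-smooth)
drift such as lock-mass steps, missingness mechanisms beyond detection
thresholding, heavy-tailed or multiplicative-burst noise, and any real
biology. The noise distribution is a design choice (no instrument-level
distribution is prescribed by the procedure itself); log-normal was chosen
because RSD-based metrics and PQN both presuppose multiplicative error.

## Scan processing

Replicate-scan clusters are formed greedily in ascending m/z (a peak joins
the open cluster while within the ppm tolerance of its running mean) — a
deterministic, oracle-checkable stand-in for vendor clustering; a cluster
survives with peaks from ≥2 distinct scans and ≥⌈0.6 × 3⌉ scans, keeping
the intensity-weighted mean m/z (weights chosen so high-S/N scans dominate)
and mean intensity. Window overlaps resolve to the window whose centre is
nearer the peak. Alignment is single-linkage in ppm space over the pooled
sorted m/z values; one peak per sample per feature (nearest to the feature
median), feature m/z = member median.

## Problem sizes and numerical conventions

Default synthetic studies are desk-scale: ~300 features, 3 plates × 30
wells, 14 QCs, 4 blanks (the acceptance checks scale some dimensions: 500
QCs for the RSD closed form, 300–1000 features for the null calibration).
All tolerances are ppm-relative for masses; the MAD scaling is the stated
1.4826 (not 1/Φ⁻¹(3/4) to full precision); filter comparisons use `≥` for
presence and `>` for sparsity; ties in IS selection break to smallest
|ppm error|; argmin over the LOOCV grid takes the first minimum. The glog
base is natural log (base only rescales the transformed values). Manifests
contain no timestamps so reruns are byte-identical.

## Known limitations

Single-IS screening cannot separate IS-specific pipetting error from
infusion failure; there is no multivariate multi-IS mode. Drift is fitted
per run, not per scan. No vendor RAW/mzML ingestion — scan-level input is
delimited text. Annotation is level-4 putative by accurate mass only
(no isotope scoring or MS/MS). Blank subtraction's fold multiplier is a
convention, not a prescribed value, and is exposed in config. The PCA
outlier pass assumes an approximately elliptical within-class score
distribution on two components.
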