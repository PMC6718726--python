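# Methods

This note documents the models, parameter choices and numerical conventions
behind `radiosurv`, and what the synthetic data used by the test suite does
and does not establish.

## Inputs and preprocessing

A study is four co-registered, skull-stripped 3-D volumes (T1, T1-Gd, T2,
T2-FLAIR) at isotropic spacing plus an integer label volume in the post-2017
BRATS convention: 0 background, 1 necrosis/non-enhancing core, 2 peritumoral
edema, 4 enhancing tumor (a reader flag maps the older dialect, 3 → 1).
Decoded sub-regions are nested by construction: whole tumor WT = {1,2,4},
tumor core TC = {1,4}, active tumor AT = {4}. The brain mask is the nonzero
support of the T1 channel (tumor voxels are included by definition).
Registration, resampling and skull-stripping are out of scope — inputs are
assumed already preprocessed.

**Intensity standardization.** Each channel is independently standardized
against its own brain statistics: values are clipped to [μ−3σ, μ+3σ] (μ, σ
the mean and population SD over brain voxels), mapped affinely to [0, 255]
and rounded half-up. This makes the result exactly invariant to positive
affine intensity transforms — the scanner's gain and offset drop out — at
the cost of not preserving relative grey-level differences. Per-channel
(rather than pooled) statistics are a documented choice, not a claim about
the original analysis, which does not specify it. Zero σ over the brain is
an error, not a silent pass-through.

**Survival classes and split.** Overall survival is grouped as SHORT
(<10 months), MEDIUM (10–15 months, both boundaries inclusive) and LONG
(>15 months), with one month = 30.4375 days (Julian year / 12; the
thresholds are defined in months only, so the day conversion must be fixed
somewhere — it is a single configurable constant). The discovery/validation
split sorts records by survival (stable, tie-broken by patient id) and sends
every third record (1-based rank divisible by 3) to validation: n = 163
yields 109/54 and both cohorts cover the full survival range.

## The 147-feature catalogue

Features are computed per (sub-region, modality) pairing — WT on T2-FLAIR,
AT on T1-Gd, TC on T2 — on the axial slice with the largest in-slice tumor
area (ties to the lowest index), after cropping to the mask's tight bounding
box. 48 features per pairing and 3 joint volume ratios give
3 × 48 + 3 = 147. Within a block the order is: 14 shape, 14 intensity,
14 GLCM, 3 HOG, 3 LBP; blocks are ordered T2-FLAIR/WT (F1–48), T1-Gd/AT
(F49–96), T2/TC (F97–144), joints (F145–147). Names are
`Modality_Region_FeatureName_F<index>`; the full order ships as a JSON
manifest (`write_feature_manifest`).

- **Shape (14):** tumor and brain volumes in mm³ (3-D voxel counts × voxel
  volume) and their ratio; convex, filled, tumor and brain areas on the
  selected slice; tumor/brain area ratio; eccentricity, orientation
  (major-axis angle, degrees in (−90, 90]), equivalent diameter, solidity,
  extent, perimeter — all via `skimage.measure.regionprops`, with every
  in-mask pixel treated as one region regardless of connectivity.
- **Intensity (14):** first-order statistics of the in-mask grey levels of
  the selected slice (not the 3-D region — the single-slice convention is
  applied consistently): min, max, median, mean, range, variance (n−1),
  2nd and 3rd central population moments, 256-bin histogram entropy in
  bits, non-excess kurtosis, RMS, skewness, SD (n−1), mean absolute
  deviation.
- **GLCM (14):** grey levels are quantized to 8 by uniform binning of
  [0, 255]; co-occurrence counts include only pixel pairs with both ends
  inside the mask, symmetrized and normalized to sum 1. Nine statistics
  (contrast, correlation, energy, homogeneity, sum variance, sum average,
  mean variance, mean autocorrelation, entropy) come from the 0° matrix
  (offset (0,1)); the four "…2" statistics — sum entropy2, difference
  entropy2, sum variance2, difference variance2 — come from a single matrix
  whose counts are accumulated over the 0° and 45° offsets {(0,1), (−1,1)},
  which makes them measurably less sensitive to texture orientation (a
  tested property). Averaging the two single-offset values instead of
  accumulating counts is exposed as a flag. The 14th value is the range
  (max − min) of the other 13.
- **HOG (3):** sum, median and SD of the oriented-gradient descriptor
  (9 orientation bins, 8×8-pixel cells, 2×2-cell blocks, background zeroed;
  patches smaller than one block are zero-padded to 16×16).
- **LBP (3):** sum, mean and SD of the normalized 59-bin uniform
  local-binary-pattern histogram (8 neighbors, radius 1) over in-mask
  pixels, with out-of-mask pixels still serving as neighbors. The coding is
  computed in-package with exact unit-circle geometry — axial samples are
  the pixels themselves, diagonal samples at ±√½ are bilinearly
  interpolated, and each sample is compared to the center via the
  difference so exact grey-level ties are exact zeros (library
  implementations break such ties through ~1e−16 trigonometric coordinate
  noise, which matters on 8-bit images where ties are routine). Note that
  on a normalized histogram the sum is identically 1 and the mean 1/59;
  these two catalogue entries are therefore constants and the downstream
  MAD filter removes them, which is the filter behaving as specified.

**Empty-region policy.** An empty TC or AT (or a region with no valid
co-occurrence pair) sets its affected features to 0 and records the fact in
a per-patient QC log; the feature matrix stays rectangular at 147 columns.

**Slice-selection ambiguity.** The rule implemented is "axial slice of
maximal area". A reading in which the globally largest cross-section over
all three planes is found first has no well-defined follow-up ("then take
the transverse slice" of what?), so it is documented here rather than
exposed as a flag with invented semantics.

## Feature selection

The MAD filter removes columns whose median absolute deviation is exactly
zero — constant for more than half the cohort (e.g. [1, 1, 1, 100] is
removed despite nonzero variance). LASSO then fits a Gaussian linear model
of survival days on the standardized (zero-mean, unit-SD) features over 100
log-spaced penalties from λ_max (smallest penalty giving the empty model)
down to 10⁻³ λ_max. Ten-fold cross-validation — folds stratified by
survival class, seed-controlled — scores each λ by held-out squared-error
deviance; λ_opt minimizes the mean CV deviance and λ_1se (the largest λ
within one standard error of the minimum) is reported alongside. Features
with nonzero coefficients at λ_opt are the selected subset; coefficients
are mapped back to the original scale, so the kept set is invariant to
rescaling any column. A Gaussian outcome family is used for selection
(coefficient estimation is Cox's job, below); a penalized-Cox alternative
(`lasso_select_cox`, pure-L1 elastic net with held-out partial-deviance CV)
is provided as a flag.

## The risk signature

Coefficients come from an **unpenalized** Cox proportional-hazards fit
restricted to the selected features — not from the LASSO — which is what
makes per-feature Wald p-values available; a ridge-stabilized refit
(penalizer 0.1) is attempted and logged only on non-convergence. All
observations are treated as events unless an indicator is supplied (the
analysis assumes fully observed survival). The risk score is the plain dot
product Σ βᵢ·featureᵢ, linear and homogeneous by construction.

Cutoffs are derived once on the discovery cohort: the per-group score
medians overlap between survivor groups, so the thresholds are placed at
half the SHORT-group median (high cutoff) and half the LONG-group median
(low cutoff) — a 25th-percentile approximation. Applied to the published
group medians (+0.245 short, −1.009 long) this yields (+0.1225, −0.5045),
matching the published fixed cutoffs (+0.122, −0.505) to the printed
precision. Scores strictly above the high cutoff are HIGH risk (predicted
SHORT), strictly below the low cutoff LOW risk (predicted LONG); boundary
values fall to MEDIUM. Derived cutoffs are frozen and applied unchanged to
validation data. If the group medians are inverted (short-survivors scoring
lower than long-survivors) the derivation raises rather than silently
producing a backwards signature.

Evaluation: a 3×3 confusion matrix with per-class sensitivity
(TP/true-count) and false-positive rate (FP/true-non-count); survival
association via a Welch two-sample t-test of survival days between the
predicted HIGH and LOW strata (the contrast is a documented choice — the
source analysis names the test but not the comparison); and a z-score
(population-SD) transform of the selected features for heat-map display.

## Classifier benchmark

Eight fixed configurations, no tuning: linear SVM (C = 1), Gaussian SVMs
with kernel scale √P ("medium") and 4√P ("coarse", i.e. γ = 1/P and
1/(16P)), KNN with k = 100 (Euclidean), k = 10 (cosine), k = 10
(Euclidean), LDA, and a random-subspace ensemble of 200 LDA learners each
seeing ⌈P/2⌉ features and all samples. A learning-rate setting is
meaningless for subspace ensembles (there is no boosting) and is therefore
not a parameter. Multiclass SVM scores use the one-vs-one decomposition
aggregated to per-class vote margins; KNN scores are neighbor-vote
fractions; LDA and the ensemble use posterior probabilities.

Cross-validation is stratified 5-fold (non-stratified fallback, logged,
when a class has fewer members than folds), with standardization fitted
inside each training fold only; k for KNN is clamped to the training-fold
size when necessary (k = 100 requires n_train ≥ 100). Out-of-fold scores
are pooled for per-class one-vs-rest AUC (midrank ties count ½) and pooled
accuracy. The four feature sets (all features, LASSO subset, each ±
clinical factors — age plus a one-hot over GTR/STR/MISSING resection
status, MISSING being a legal category covering about half the cohort)
share one fold assignment per seed, so cells are comparable.

## Synthetic data

The phantom generator emulates exactly the structure the analysis assumes:
a brain ellipsoid (default semi-axes 28×28×20 mm in a 64×64×48 grid at
1 mm³) carrying four channels with distinct baselines; nested tumor
ellipsoids (WT/TC/AT radii 16/10/6 mm by default) with per-channel,
per-region contrast chosen so each pairing's region is brightest on its
paired channel; a ±1 checkerboard texture of period 4 voxels and
configurable amplitude (default 30 grey units — giving analytically
predictable co-occurrence structure); additive Gaussian noise (SD 5); brain
intensities clipped to ≥1 so the brain support stays well-defined.

Cohorts draw per-patient geometry (lognormal radius variation, SD 0.15 on
the log) and texture amplitude (normal, SD 10), and sample survival from an
exponential proportional-hazards model: hazard = (ln 2 / baseline median) ·
exp(Σ βⱼ zⱼ) with z the cohort-standardized generating parameters — the
simplest model consistent with a Cox analysis, with one documented scale
parameter (default median 362 days, the study cohort's median). No
censoring is generated by default (survival is treated as fully observed);
a censoring fraction exists for robustness tests. Ages are N(60, 12²)
truncated to [18, 90]; resection status is GTR/STR/MISSING with a 49%
missing fraction and GTR:STR ≈ 59:24 among known, mirroring the study
cohort's clinical table. Every generator is a pure function of its config
and seed.

The feature-level generator (`generate_feature_cohort`) skips imaging:
standard-normal decoy columns named after the canonical catalogue plus
designated effect columns drive the same survival model. It exists so the
selection, signature and benchmark stages can be exercised at cohort scale
in seconds.

**What passing tests do and do not show.** The phantoms validate the
machinery — mask decoding, normalization invariances, the feature
definitions against brute-force oracles, selection and coefficient
recovery under a known hazard, CV harness sanity. They do not emulate MRI
physics (bias fields, k-space artifacts, partial-volume effects), real
tumor morphology, or the BRATS cohort's feature distributions, so passing
tests say nothing about the clinical performance numbers of the original
cohort, which require that external accession.

## Numerical conventions and limitations

- Quantization rounds half-up (`floor(x + 0.5)`); μ maps to 128.
- Population (n-denominator) SD for normalization and z-scores; n−1 for
  the intensity variance/SD statistics; central population moments.
- Entropies in bits (log₂) throughout.
- GLCM level indices are 0..7; statistics are computed on bin indices, not
  grey values.
- Problem sizes in the statistical test suites — 50 seeds for recovery
  studies (n = 300 LASSO, n = 500 Cox), 200 replicates for null-uniformity
  and permutation checks, 100 random patches for oracle equivalence — were
  chosen to make the binomial/KS margins meaningful at suite scale.
- The Cox ±0.15 recovery band at n = 500 is ~1.6 standard errors, i.e.
  ~88% per-seed coverage; checks against it are sharp for bias or sign
  errors but should not be read as a 90%-coverage guarantee.
- Single-slice texture/intensity features discard 3-D heterogeneity by
  design; 3-D texture matrices, filtered (wavelet/Laplacian) features and
  full IBSI compliance are out of scope.
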