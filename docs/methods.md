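# Methods

`lungrp` implements a radiomics pipeline for predicting symptomatic
(grade ≥ 2) radiation pneumonitis (RP) after stereotactic body
radiotherapy (SBRT) for lung cancer, using only pretreatment planning
CT, the planned dose distribution, and the lung/GTV contours. This note
records the model, the numerical conventions, and the design choices
made where the design was genuinely open.

## Dose-threshold ROIs and DVH parameters

The analysis region for texture is not the whole lung but the lung
tissue that will actually be irradiated. Four regions of interest are
built per patient: LVx = {lung ∖ GTV voxels with dose > x Gy} for
x ∈ {0, 5, 10, 20}. The inequality is strict, so a voxel at exactly
x Gy is excluded, and the masks nest (LV20 ⊆ LV10 ⊆ LV5 ⊆ LV0). The
dose-volume histogram covariates are Vx = 100·|LVx|/|lung ∖ GTV| (%)
for x ∈ {5, 10, 20} and the mean lung dose MLD (Gy), both computed over
lung ∖ GTV for consistency with the ROI definition (whether the
clinical DVH convention includes the GTV in the denominator is
ambiguous; exclusion was chosen for internal consistency). Dose is
assumed co-registered with the CT; DICOM-RT parsing and resampling are
out of scope.

## The 486-feature radiomic vector

Per (patient, ROI) pair, 54 features are computed on the original CT
and on each of 8 wavelet subbands: 486 = 54 × 9.

**First-order (14):** mean, variance, SD, skewness, kurtosis
(non-excess), entropy (bits) and uniformity on the quantized histogram,
energy (Σx²), min, max, median, range, mean absolute deviation, RMS.

**Texture (40):** computed on gray levels quantized to Ng = 32
equal-width bins over the in-mask intensity range (min → 1, max → Ng;
affine-invariant and monotone). Four matrices:

* **GLCM (9 features):** one symmetric co-occurrence matrix merged over
  the 13 unique distance-1 3-D offsets, both voxels in-mask,
  probability-normalized. Energy, contrast, correlation, homogeneity,
  variance, sum average, entropy, dissimilarity, autocorrelation.
  Correlation = Σᵢⱼ p(i,j)(i−μ)(j−μ)/σ² with μ, σ² from the (equal)
  marginals of the symmetric matrix; σ² = 0 maps to 0.
* **GLRLM (13):** runs are maximal collinear in-mask segments of equal
  level, accumulated over the same 13 directions into one matrix.
  SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLV,
  RLV. Run percentage divides the run count by voxels × directions so a
  fully fragmented region scores exactly 1.
* **GLSZM (13):** zones are 26-connected components of equal level;
  features analogous to GLRLM with zone size in place of run length.
* **NGTDM (5):** Amadasun–King coarseness, contrast, busyness,
  complexity, strength, with neighborhood means restricted to in-mask
  26-neighbors; voxels without an in-mask neighbor are excluded.
  Coarseness is capped at 10⁶ when Σpᵢsᵢ = 0.

Feature names reuse the field's conventional abbreviations, with family
suffixes only where two families share a name (Energy vs Energy_GLCM,
Entropy vs Entropy_GLCM, GLN_GLRLM vs GLN_GLSZM, Contrast_GLCM vs
Contrast_NGTDM). Degenerate inputs (constant regions, zero-variance
marginals) map to the documented fallbacks and are logged, never NaN.

**Wavelets.** A single-level separable 3-D discrete wavelet transform
(Coiflet-1 by default, symmetric boundary padding) gives 8 subbands,
labelled x-major: label position 1/2/3 is the x/y/z-axis filter, L =
scaling (low-pass), H = wavelet (high-pass). Decimated coefficients are
aligned back to the CT grid by 2× nearest-coefficient upsampling with a
center crop, so the original ROI mask applies unchanged to every
domain. With an orthogonal wavelet and periodized boundaries the
decomposition conserves energy exactly (the Parseval check in the test
suite); the symmetric default trades that exactness for better edge
behavior on masked anatomy. Note that subband values inside the mask
depend on CT values just outside it — mask locality holds per domain,
not through the filter.

## Signatures and the balanced-subset ensemble

With ~9% positives, a single fit is dominated by the majority class.
Instead the negatives are randomly permuted (seeded) and partitioned
into K = 10 disjoint groups of size n₊ or n₊ + 1 (22·7 + 23·3 = 223
for the default cohort); each group joined with all positives forms a
balanced subset.

Per subset, features are z-standardized and a signature is selected by
repeated LASSO: each repeat draws a stratified bootstrap resample, fits
an L1-penalized logistic regression with the penalty chosen by
stratified 3-fold cross-validation (liblinear, C ∈ logspace(−2, 2, 5),
log-loss scoring), and records the features with nonzero coefficients.
Features are ranked by selection count — ties broken by mean
|coefficient|, then name — and the top 4 form the signature (4 ≈ one
tenth of the subset size, the usual overfitting guard). The repeat
count defaults to 1000; the test suite and acceptance script use 100,
which is ample for the strong planted effect. What exactly is
re-randomized across repeats is an open design point; bootstrap
resampling with per-repeat CV-chosen penalty was adopted, applied per
subset. A final L1 logistic fit on the subset's signature columns gives
the member model; the ensemble probability is the arithmetic mean of
the K member probabilities.

The DVH baseline runs the identical machinery on the 4-parameter pool
{V5, V10, V20, MLD}, except that the selection unit is the whole
combination of parameters with nonzero coefficients: the most frequent
nonempty combination (ties: fewer parameters, then name) is kept.

## Evaluation

AUC is the trapezoidal area under the ROC (equivalently the
Mann–Whitney pair statistic; ties count ½). Sensitivity, specificity
and accuracy are TP/(TP+FN), TN/(TN+FP) and (TP+TN)/n; a probability
exactly at the operating threshold classifies positive. The operating
threshold is Youden's index on the training ROC, frozen when scoring
the test cohort; a fixed 0.5 rule is available. Which rule produced the
published operating points of the study this pipeline emulates is not
stated, so both are exposed and neither is asserted as canonical.

## The synthetic cohort generator

No imaging data is shipped; every experiment runs on seeded synthetic
patients designed to carry the statistical structure the analysis
assumes, at planning-CT-like scale: 48³ grids, (2.0, 1.0, 1.0) mm
spacing, lung baseline ≈ −800 HU-like units with sd 50, dose peak 48 Gy
(a typical SBRT prescription). Per patient: an ellipsoidal lung with
jittered axes, a 2.5–4.5-voxel spherical GTV strictly inside it, and a
radial Gaussian dose about the GTV centroid (falloff 8 voxels, ±25%
per-patient jitter; distances in voxel indices, matching the falloff's
voxel units). The Gaussian dose is monotone in distance, so the LVx
masks nest by construction, and Vx/MLD vary across patients through the
geometry and falloff jitter — but independently of the RP label, so the
DVH baseline has no real signal to find.

**Planted effect.** Lung texture is Gaussian white noise smoothed with
a kernel of sigma 1.5 voxels (RP-positive) vs 0.7 voxels (RP-negative),
±15% per patient, then renormalized to the target sd: positives have
higher voxel-neighbor correlation, the direction the GLCM correlation
feature measures. Two label-independent nuisance sources are layered on
top, emulating inter-patient and inter-scanner amplitude variability:
a multiplicative noise-amplitude jitter (0.6–1.4×) and a signed-power
contrast-response exponent γ ∈ (0.6, 1.8) applied to the normalized
field. These matter: without them every patient shares one exact noise
amplitude, and absolute-amplitude statistics (subband SD/RMS/energy)
would separate the classes even more sharply than neighbor correlation
— a degenerate feature of the simulation, not of lungs. The
monotone-in-intensity nuisances leave spatial rank structure (hence
correlation) nearly untouched while decorrelating amplitude-based
features from the label, so the recoverable effect is the planted one.

**What the generator does not emulate:** real airway/vascular anatomy,
respiratory motion, scanner reconstruction kernels, HU calibration, or
any real dose–toxicity relationship (dose geometry is label-free by
design). Passing tests therefore demonstrate that the pipeline recovers
a known texture effect under realistic nuisance variation and class
imbalance — not that the published clinical AUCs are reproduced, which
would require the undeposited patient cohorts. The effect magnitude is
a free parameter of the simulation; only its direction is anchored.

## Problem sizes and determinism

The acceptance study runs at the emulated design's full size — 245
training (22 RP) and 30 test (8 RP) patients, 48³ grids, LV5 features,
10 subsets × 100 LASSO repeats — in roughly five minutes on one CPU;
unit tests use 16³ grids and toy cohorts. All randomness flows from
master seeds through `numpy.random.SeedSequence`, liblinear is given a
fixed `random_state`, and CV folds are unshuffled, so two runs with one
seed are bit-identical end to end (feature tables, signatures,
coefficients, reports).

## Known limitations

* The 54-feature list follows the MATLAB radiomics-package convention
  the emulated design cites; its exact supplementary list (and any
  preprocessing such as HU clipping or resampling) is not public, so
  the adopted set is an informed assumption.
* Quantization depth (32), wavelet basis (coif1) and connectivity
  conventions are configurable defaults, not validated against the
  original implementation.
* GLRLM/GLSZM normalizations across merged directions differ between
  published toolkits; the conventions here are documented above and
  pinned by enumeration oracles in the tests.
* The synthetic planted effect is far stronger than any plausible
  clinical texture biomarker; performance numbers on synthetic cohorts
  say nothing about clinical performance.
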