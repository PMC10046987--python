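# Methods

This note documents the models, conventions and numerical choices behind
`iristex`, and what the synthetic benchmark does and does not establish.

## Coordinate and angle conventions

Images are `(row, column)` arrays with `x = column`, `y = row`. All angular
quantities use a *clock convention*: angle 0 points to 12 o'clock (up in
the displayed image) and increases clockwise, so 3 o'clock is the +x
direction. One clock hour is 30°. This makes iridology-chart sectors
contiguous intervals of the angular axis everywhere in the package; the
heart sector of a left iris spans 60°–120° (2–4 o'clock).

## Segmentation (integro-differential operator)

The pupil and limbus are modeled as circles. For a candidate circle
`(x0, y0, r)` the detector evaluates the circular mean intensity
(bilinear interpolation at `n_angular_samples` equally spaced angles,
optionally excluding `arc_mask` intervals), differentiates that profile
with respect to radius by central differences, smooths with a discrete
Gaussian of standard deviation σ (default 1 radius step), and takes the
absolute value. The boundary circle maximizes this response.

Search ranges default to anatomical priors: pupil radius in
`[min_dim/40, min_dim/8]`, iris radius in `[1.5, 5] ×` the found pupil
radius (capped to stay inside the image), iris center within ±15 px of the
pupil center. An optional eyelid mask excludes ±45° around 12 and 6
o'clock from the limbus integral (off by default; the synthetic eyes have
no lids).

The full grid is O(W·H·R) and needless at camera resolution, so the
default search is staged:

1. **Coarse scan** of a 4× block-averaged image over all centers and
   scaled radii.
2. **Non-maximum suppression** on the coarse score map, keeping a generous
   candidate pool. Block averaging makes small sharp blobs (lesions, fiber
   junctions) score disproportionately high at coarse scale, so the coarse
   ranking is treated as a shortlist, never as the decision.
3. **Full-resolution re-scoring** of each pooled candidate at its center.
   For the pupil search, candidates whose disc interior is more than
   `interior_tolerance` (default 25 gray levels) brighter than the darkest
   candidate's are pruned — the pupil is by construction the dark disc,
   and this removes limbus-grazing arcs and bright-texture artifacts.
4. **Box refinement** around the strongest candidates (half-width matching
   the suppression radius, so a true center suppressed by a nearby blob
   remains reachable), followed by a unit-stride polish.

Ties break toward smaller radius, then row-major center order, making the
result deterministic. An `exhaustive` strategy evaluates the full grid and
is used in tests to verify that the staged search returns the identical
circle on small images.

## Normalization and ROI

The rubber-sheet map samples the image at
`x(r,θ) = (1−r)·x_p(θ) + r·x_l(θ)`, `y(r,θ) = (1−r)·y_p(θ) + r·y_l(θ)`,
with `r = i/(rows−1)` over 360 rows and θ over 720 columns (0.5°/column).
Row 0 is therefore the pupil boundary and the last row the limbus. With
720 angular samples the 60° heart sector is exactly 120 columns, which
matches the 190 × 120 ROI width and motivates the (rows = radial,
columns = angular) reading of the normalized size. Sampling is bilinear;
points falling outside the source image are filled with the nearest edge
value and flagged in a validity mask.

The ROI's radial anchor is row 60 (of 360): the window skips the innermost
60 rows (pupil-border ring, where unwrapping distortion is largest) and
the outermost 110 rows (limbus transition). The anchor is configurable;
the crop itself is a pure slice (modular in the angular axis), never a
resample. CLAHE follows the crop and uses 8 × 8 tiles with a clip limit of
2.0 expressed as a multiple of the uniform 8-bit histogram height (mapped
internally onto scikit-image's normalized clip parameter with 256 bins).
A constant ROI is returned unchanged so no contrast is ever invented.

## Texture features

One level of a separable 2-D DWT (Haar by default; orthogonal, exact
halving of the even ROI dimensions) with periodized boundaries splits the
ROI into cA, cH, cV, cD. Periodization keeps the transform non-redundant,
so coefficient energy equals input energy and inverse reconstruction is
exact — both are asserted in tests. The 190 × 120 ROI yields 95 × 60
sub-bands.

Per band, in fixed order (bands cA, cH, cV, cD):

- **5 first-order statistics** — mean; standard deviation (1/(N−1));
  Shannon entropy in bits of the 256-bin min–max histogram; skewness
  `m3/m2^1.5`; kurtosis `m4/m2²` (biased moment ratios, non-excess).
  Constant bands return (c, 0, 0, 0, 0) by convention.
- **22 GLCM features**, averaged over the four directions 0°/45°/90°/135°
  at distance 1 on the band quantized to 8 levels: autocorrelation,
  cluster prominence, cluster shade, contrast, correlation, difference
  entropy, difference variance, dissimilarity, energy, entropy,
  homogeneity, the two information measures of correlation, inverse
  difference moment, maximum probability, sum average, sum entropy, sum of
  squares, sum variance, maximal correlation coefficient, inverse
  difference normalized, and inverse difference moment normalized.
- **7 GLRLM features**, averaged over the same four directions at 16
  levels: SRE, LRE, GLN, RP, RLN, LGRE, HGRE, with run percentage =
  (number of runs)/(number of pixels) and 1-based gray-level indices in
  the low/high gray-level emphases.

Conventions worth making explicit:

- Detail-band coefficients are signed, so both co-occurrence and run-length
  stages quantize by uniform min–max binning; a constant band maps to
  level 0.
- The GLCM accumulates symmetrically (each pair plus its reverse), which
  equalizes the marginals; normalization divides by the total count.
- All entropy-like features use base-2 logs with `0·log 0 := 0`. The
  first information measure of correlation is defined 0 when
  `max(HX, HY) = 0`; the second clamps its argument at 0 before the
  square root. Correlation is defined 0 when a marginal is degenerate.
- The maximal correlation coefficient is `sqrt(λ₂(Q))` with zero-marginal
  levels dropped before forming Q and the eigenvalue clipped to [0, 1];
  the plain-λ₂ form is available via `FeatureConfig(mcc_sqrt=False)`.
- Cluster prominence uses the third power of `(i + j − 2μ)` and cluster
  shade the fourth. Much of the literature swaps these two names; the
  positional content of the feature vector is unaffected either way.
- Gray levels are indexed 1..L in all moment-type features, and the
  overall GLCM mean μ is the average of the two marginal means (equal
  under symmetric accumulation).

The fused vector is 4 × (5 + 22 + 7) = 136 values with stable names
(`<band>_<feature>`), asserted identical across runs.

## Feature selection

ReliefF, two-class form: every sample is used (m = n); for each sample its
k = 10 nearest hits and k nearest misses under Manhattan distance on
min–max-scaled features update each feature weight by
`Σ diff(misses) − Σ diff(hits)`, normalized by `m·k`, keeping all weights
in [−1, 1]. Neighbor ties break by sample index, so rankings are exactly
reproducible; a seed parameter is accepted for interface stability. When a
cohort is too small for 10 neighbors per class, the pipeline clamps k to
(smallest class − 1). Top-k selection takes ranking prefixes, so the
25/50/75 groups are nested by construction. Feature–label association is
also reported as the point-biserial (Pearson) correlation per feature.

## Classifier registry and evaluation

The 22 presets mirror the "point-and-click" preset families common in
commercial ML environments, with hyperparameters implied by the names:
trees with 100/20/4 maximum splits (fine/medium/coarse); Gaussian naive
Bayes and a kernel naive Bayes (per-feature Gaussian KDE with Silverman
bandwidth, implemented in-package because scikit-learn has no
kernel-density naive Bayes); SVMs with linear, quadratic, cubic and
Gaussian kernels at scales `√P/4, √P, 4√P` (P = feature count, C = 1);
kNN with k = 1/10/100 plus cosine, cubic-Minkowski and distance-weighted
variants (k clamped to the training size); and L-BFGS multilayer
perceptrons with layouts 10 / 25 / 100 / (10,10) / (10,10,10).

Evaluation is stratified 5-fold cross-validation with a fixed shuffle
seed. Scale-sensitive families (SVM, kNN, NN) are z-scored inside each
training fold; trees and naive Bayes see raw features. Per fold the
confusion matrix (CAD = positive) yields accuracy, sensitivity,
specificity, precision, F1 and the geometric mean `√(SNS·SPC)`, with any
0/0 ratio reported as 0 and flagged; AUC uses each family's natural
continuous score (SVM decision values, posteriors otherwise). Reported
values are fold means. Stratification is used because at cohort sizes of
tens per class unstratified folds make per-fold metrics extremely noisy.

ReliefF ranking is computed once on the full cohort and the top-k subset
is then cross-validated — deliberately matching the protocol this kind of
study reports. Note this leaks label information into the feature subset,
so small-cohort accuracies after selection are optimistic; the package's
own null-cohort calibration check therefore evaluates the full,
selection-free feature table.

## Synthetic benchmark

`generate_eye` renders: a bright sclera (default 215), an iris annulus
(base 125) carrying sinusoidal angular fiber striation (amplitude ~16 gray
levels, 24–48 cycles/revolution) plus smoothed Gaussian grain, and a dark
pupil disc (35), all with ~1.5 px soft edges. Cohorts randomize geometry
(320 × 320 images, pupil radius 28–38 px, iris 100–122 px, centers jittered
a few px) and intensities within realistic ranges. The diseased class
additionally receives 8 dark elliptical lesions (axes 2–6 px, contrast =
the cohort's `effect` parameter, 70 gray levels for a "strong" effect)
placed *in polar coordinates* inside the heart sector and mid-radial band,
guaranteeing by construction that the class signal lands inside the
cropped ROI. Everything is a pure function of the seed.

What the benchmark shows: that the implemented chain — localization,
unwrapping, the exact ROI geometry, the 136-feature descriptor, ReliefF
and the evaluators — can recover a texture difference confined to the
heart sector (best SVM cross-validated accuracy reaches 1.0 at effect 70
with 50 eyes per class, and a null cohort stays at chance). What it does
not show: anything about real irises or CAD. Real eye photographs add
eyelid/eyelash occlusion, specular highlights, non-circular boundaries,
illumination gradients and camera noise, none of which are modeled; the
lesion model is an artifact of the benchmark, not a claim about iridology.

## Problem sizes and determinism

Default experiment sizes were chosen to keep a full synthetic study small:
cohorts of 50 + 50 eyes for effect recovery, 25 + 25 for the null
calibration, 40 eyes for segmentation-recovery rates, and 128 × 128
phantoms for the staged-vs-exhaustive search equivalence. All randomness
(cohort generation, CV shuffling) flows from explicit integer seeds, and
reruns with the same seed are byte-identical through the whole pipeline.

## Known limitations

- Circle-only boundary model; no active contours or ellipse fitting.
- No occlusion handling beyond the optional eyelid arc mask.
- The GLCM quantization rule (min–max, uniform) and symmetric accumulation
  are one reasonable convention among several; both are configurable.
- Kernel naive Bayes assumes feature independence and uses a fixed
  Silverman bandwidth with a floor for near-constant features.
- AUC is averaged per fold, not pooled; with small test folds the two
  differ.
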