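# Methods

This note documents the models, numerical choices and limitations of
`cellcycle3d` at the level of detail a user needs to interpret its output.

## Problem setting and assumptions

The package classifies *segmented* nuclei: the unit of analysis is a
labelled object in a 3D stack, defined by an integer label mask produced
upstream. Segmentation quality is taken as given; touching objects with
distinct labels stay distinct and single-label connectivity is not
enforced. Stacks are in (z, y, x) order with physical voxel sizes supplied
by the user (default 0.1 × 0.1 × 0.44 µm — a typical confocal setting with
strong z anisotropy). TIFF resolution tags are not trusted: dialects vary
too much; a conflicting tag only triggers a warning.

## Geometric features

**Volume** is the voxel count times the voxel volume — exact by
definition on the digitized object.

**Shape-based interpolation.** Surface estimates on anisotropic grids are
orientation-biased, so the binary mask is first resampled to isotropic
voxels (target = the finest native axis, so in-plane resolution is never
discarded; config key `isotropic_target_um`). The mask's signed Euclidean
distance field (negative inside; per-axis physical sampling) is resampled
by trilinear interpolation and thresholded at zero, with ties counted
inside. Output samples are *cell-centred*: sampling fine-grid voxel
centres at coarse voxel centres systematically inflates volume by a
half-voxel shell (~5% on a radius-10 sphere refined 2×); centring removes
the bias. The zero level sits on voxel faces, so a 0.44 µm slab resampled
at 0.1 µm becomes 4–5 voxels thick. Single-voxel objects pass through as
an isotropic block of equivalent physical extent. Only the mask is
resampled; intensity features always use the native grid.

**Surface area** uses a weighted 2×2×2 configuration estimator: the 256
local binary configurations are histogrammed and dotted with a fixed
weight table (units of spacing²). The table was fitted once by nonnegative
least squares on digitized half-spaces of many orientations (counted in a
ball window where the true plane–ball intersection area is known in closed
form), digitized spheres (r = 15–35) and boxes/slabs, on relative areas.
Two deliberate choices: the flat-face configuration is pinned to exactly 1
(its analytic axis-aligned value, which random orientations almost never
probe), and configuration classes are orbits of the 48 cube symmetries
*without* foreground/background complementation — a convex 2-voxel edge
(box rim) and its concave complement carry genuinely different area, and
merging them underestimates boxes by ~10%. With the frozen table, errors
are ≤ ~1.5% on spheres (r ≥ 10), ≤ ~0.5% on cubes and thin slabs, and
≤ ~5% for individual plane orientations. Isolated single voxels produce
only zero-weight corner configurations and fall back to face counting
(6 s²). A plain face-count estimator is available
(`surface_estimator="face_count"`) for exact-arithmetic checks; it
overestimates curved surfaces by up to ~50% and is not used in production.
`calibrate_surface_weights()` reproduces the frozen table.

**Sphericity** is Wadell's ψ = π^{1/3}(6V)^{2/3}/A: the area of the
volume-equivalent sphere over the estimated area; 1 for a ball, ~0.806 for
a cube. Digitization can push estimates a few % above 1.

**Eccentricities** come from the covariance of the physical coordinates of
the mask voxels (binary, not intensity-weighted — intensity asymmetry is
captured separately by the centroid deviation). With eigenvalues
λ1 ≥ λ2 ≥ λ3, E1 = √(λ3/λ1) and E2 = √(λ2/λ1). Ellipsoid semi-axes scale
as √λ, so both ratios are in [0, 1]; an oblate metaphase plate has E1 ≪ 1,
E2 ≈ 1.

**Surface-to-centroid distances** use the 6-connected boundary (stack
border counts as outside) and physical distances to the unweighted
centroid; the std is population (divide-by-m), as everywhere in the
package.

## Intensity features

Mean and population std over mask voxels, plus the signed difference
(dx, dy, dz) between the intensity-weighted and geometric centroids in µm.
Signs are kept — orientation is information; selection can discard it.
All three components are stored, but the canonical 42-feature set counts
the deviation once (z only): apical–basal asymmetry, e.g. condensed
heterochromatin at one end of an interphase nucleus, is the biologically
loaded component. This also resolves the feature count: 7 shape + 2
intensity moments + 1 deviation + 32 texture = 42, while the full table
carries 44 columns.

## Texture features

Intensities are min–max quantized per object to `glcm_levels` = 256 bins
(constant objects map to bin 0), which makes all texture features
invariant to affine intensity rescaling regardless of input bit depth.
Co-occurrence matrices are accumulated along the 13 unique directions of
the 26-neighbourhood at displacement `glcm_displacement` = 1, counting only
pairs with *both* voxels inside the mask, symmetrized and normalized to
sum 1. Directions with no valid pair are flagged empty and excluded from
aggregation (zero-imputation would make thin objects' statistics
orientation artefacts); an object with no valid pair in any direction is
excluded from the dataset with a logged reason.

Sixteen statistics are computed per direction with the canonical
conventions: natural logarithms; 0·log 0 = 0; correlation and information
measure 1 are 0 in their degenerate cases (σx σy = 0, HX = HY = 0).
Sum variance is the variance of p_{x+y} about the sum average (the widely
adopted correction of the original definition's self-reference to sum
entropy); difference variance is the variance of p_{x−y}. HXY2 is
evaluated through the product-marginal identity HXY2 = HX + HY, which is
exact for normalized marginals and is verified against a naive double-sum
oracle in the tests. Features are the mean and population std over
non-empty directions (32 values).

Known bias, by design: offsets are voxel units, so a z-step spans 4.4×
the physical in-plane step at the default voxel size. The native
acquisition grid is the convention; texture features are therefore
comparable only between objects sampled at the same voxel size.
Displacements 2/4/8 are supported but not default.

## Classification

All classifiers sit behind a per-fold `StandardScaler` (feature units span
µm³ to dimensionless; the kernel methods are scale-sensitive). Labels are
integer phase codes 1–5 in the order interphase, prophase, metaphase,
anaphase, telophase.

* **SVM** — RBF kernel, γ = 0.001953, C = 512 (tuned values from the
  motivating study; both overridable), libsvm one-vs-one multiclass.
* **Weighted SVM** — per-class costs `w_c ∝ 1/√n_c`, normalized so
  Σ w_c n_c = Σ n_c (the normalization is this package's choice; only the
  proportionality is inherited). Weights are recomputed from the training
  labels at every fit, so cross-validation applies the rule per fold.
* **PNN** — Gaussian kernel density per class with shared width σ;
  prediction by maximal summed kernel (equivalent to frequency priors).
  Default σ is tuned by internal stratified 5-fold CV on a log grid
  (10^−1…10^1, seed-fixed). The wrapper-selection scorer instead uses a
  fixed σ = 1.0 on z-scored features: tuning inside every greedy candidate
  evaluation would multiply the cost ~40× for no ranking benefit.
* **KNN** — K = 10, Euclidean on standardized features; ties resolve to
  the smallest class code.
* **BPNN** — one hidden layer of 25 logistic units, softmax output,
  seed-fixed initialization.

**Evaluation** is stratified k-fold (default 10) with shuffling fixed by
seed; stratification matters because minority phases are ~4–5%. If a class
has fewer members than folds, the split degrades to plain shuffled k-fold
with a warning. The confusion matrix is accumulated over folds (true ×
predicted over all five phases); per-class accuracy is row recall; overall
accuracy is the micro-average trace/total. Conservation (row sums = class
counts) is asserted in the tests on every report. Identical seed, data and
spec reproduce reports bit-for-bit.

## Reduction and selection

PCA and Fisher LDA wrap scikit-learn (LDA dimension ≤ classes − 1 = 4;
singular within-class scatter falls back to a shrinkage solver, logged).
Classical (Torgerson) MDS is implemented in-package because reduction runs
inside cross-validation and needs an out-of-sample rule: fit double-centres
the squared Euclidean distance matrix and keeps the leading non-negative
eigenpairs; new points project through the Gower interpolation formula,
which reproduces the training embedding exactly on the training points. On
Euclidean data the embedding equals PCA scores up to sign (asserted
numerically). Default output dimensions: 8 for PCA/MDS, 4 for LDA.

Wrapper selection is greedy forward/backward search scored by stratified
CV accuracy with folds fixed once per run. Ties break towards the earliest
feature in canonical column order, making runs fully reproducible. The
search runs to the requested size and reports the *best prefix* rather
than stopping at the first non-improvement — the full trace is the
interesting object (accuracy rises, plateaus, then degrades as noise
features dilute the distance metric).

## Synthetic phantoms

The generator renders the five phase morphologies as parametric solids
(ellipsoids and two-lobe unions, randomly oriented) on the anisotropic
default grid, one nucleus per rendering box on a single-layer grid (an
embryo-surface-like arrangement), so every geometric ground truth is known
analytically. Intensity is a base level (≈400 photons) modulated by a
smoothed-noise speckle field of per-phase contrast, an optional bright
off-centre subregion along z for interphase (heterochromatin proxy,
present with p = 0.7), Poisson shot noise and Gaussian read noise (σ = 8);
the noise levels keep 256-level quantization non-degenerate.

Defaults encode the biology: nuclei ~4 µm diameter; interphase-dominant
mix (0.58/0.04/0.13/0.05/0.20) with prophase and anaphase as ~4–5%
minorities; metaphase plates oblate (short-axis fraction 0.33 ± 0.07, so
E1 < 0.5); anaphase lobes partially separated, telophase lobes compact and
well separated but kept as one object. Parameter ranges of adjacent phases
overlap deliberately — phase transitions are gradual, with no sharp
morphological boundary — and the overlap widths were calibrated once so
that an unweighted SVM reproduces the difficulty regime reported for live
embryo data (overall accuracy in the mid-90s with strongly depressed
minority recalls) rather than a trivially separable task. At n = 2000 the
weight rule then lifts prophase recall by ~10–20 points and anaphase by a
few points at ≤ ~1.3 points overall cost; the anaphase effect is
directional but not guaranteed at every seed (at some seeds its recall is
unchanged).

The `StageShift` presets emulate a developmental covariate shift: stage B
elongates interphase envelopes 1.6× along z (apical–basal elongation after
cellularization), scales sizes 1.1×, intensity gain 1.5× and speckle
contrast +0.1. Training on one stage and testing on the other drops
overall accuracy by tens of points; pooling both stages recovers both
within a few points — the qualitative robustness argument for training
across conditions.

What the phantoms do *not* emulate: real chromatin substructure,
segmentation errors (over/under-segmentation, partial nuclei at stack
borders), depth-dependent attenuation, photobleaching, or temporal
correlation between time points. Passing tests therefore demonstrate the
correctness of the feature suite and the directional phenomena of
weighting, transfer and selection — not field performance on any
particular microscope or tissue.

## Visualization

Validation overlays draw the z-projected silhouette contour of each object
(red) on the 1st–99th-percentile contrast-stretched MIP (display only;
analysis values untouched), with the class code at the projected centroid:
white when prediction matches truth, black "(predicted, actual)" on
mismatch, plain white codes in prediction-only mode.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale, chosen to keep the
statistics meaningful: the imbalance study at n = 2000 (fixed seed), the
stage-transfer study at n = 600 per stage, the end-to-end pipeline at
n = 1000 (run twice to confirm bit-reproducibility), selection on
500 × 26 feature matrices, and oracle solids at radii 10–40 voxels.

## Known limitations

* The 2×2×2 surface estimator cannot distinguish a box edge from a
  staircase step locally; box-edge area converges as O(1/side) (≈ −2% at
  side 30). Orientation-specific plane errors reach ~5% even though the
  orientation average is ~0.2%.
* GLCM offsets ignore physical anisotropy (above).
* The PNN stores its training set; prediction is O(n_train · n_test · d).
* Classical MDS is O(n²) memory in the training size.
* The reduced `paper9` preset contains eight features.
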