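# Methods

`wbovw` implements a weighted bag-of-visual-words (WBOVW) pipeline for
classifying circular regions of interest (ROIs) of placental ultrasound
images as *normal* or *FGR* (fetal growth restriction). The clinical
motivation is texture: FGR placentas tend to show short rod-like texture
while normal placentas show dot-like granular texture, a contrast that is
subtle at early gestational ages and buried in speckle noise. The pipeline
turns each ROI into a fixed-length histogram over a learned vocabulary of
local texture patterns and classifies that histogram with a small ensemble.

## Model and procedure

**Preprocessing** (`imaging_io`). Images are 8/16-bit grayscale PNG/TIFF
rescaled to [0, 1]; the ROI circle (center, radius in pixels, from the
annotation manifest) is cropped to a (2r+1)-square with a boolean validity
mask over the inscribed circle. Denoising is soft-threshold wavelet
shrinkage (bior2.2, 2 decomposition levels, VisuShrink universal threshold
with the noise scale estimated from the finest detail level); the
universal threshold is derived for orthogonal bases, and we accept the
small approximation of using it with a biorthogonal pair. Histogram
equalization uses the 256-bin CDF of masked-in pixels only, so the mask
edge contributes no artificial contrast. Training images may additionally
be augmented (brightness ±0.1, contrast ×[0.9, 1.1], rotation ±15°,
random crop retaining 90% of the area resized back, 2 copies per image by
default); deliberate *absence* of scaling/affine/shear preserves primitive
size, which is the class signal. Augmentation is applied to the training
split only, after splitting.

**Keypoints** (`scale_space`). A Gaussian scale space with n_octaves = 4,
s = 3 intervals (scale factor k = 2^(1/3)), base σ₀ = 1.6; each octave
holds s+3 levels σᵢ = σ₀kⁱ smoothed directly from the octave base
(half-width ⌈3σ⌉ kernels, reflect padding), and the σ = 2σ₀ level,
decimated 2×, seeds the next octave. Adjacent levels are subtracted into
the difference-of-Gaussians (DoG) stack, and a voxel is a keypoint iff it
is a *strict* extremum over its 26 scale-space neighbours and
|D| ≥ 0.01. Strictness rejects plateaus; there is no edge-response test
and no sub-pixel refinement — detection is deliberately the minimal
extremum rule, with the contrast threshold exposed in configuration.
Note the detectable blob width is bounded below by the interior scale
levels: a width-w blob peaks near σ ≈ w/√k, so structures much narrower
than ~2 px surface only through octave-0 boundary levels and are not
reported.

**Descriptors** (`hog_features`). Gradients are unscaled central
differences Gx = I(x+1,y) − I(x−1,y), Gy = I(x,y+1) − I(x,y−1) (one-sided
at borders), orientation folded to [0°, 180°). The window around a
keypoint has side max(16, round(6σ)) rounded up to a multiple of 4, split
into a 4×4 grid; each cell accumulates gradient magnitude into nine
20°-wide bins by *hard* assignment (all mass to the bin containing φ) and
is L2-normalized as v/√(‖v‖² + ε²) with ε = 1e−6, so zero-gradient cells
stay zero. The 16 cells concatenate to 144 dimensions. Normalization per
sub-region (rather than over the whole 144-vector) is our reading of the
ambiguous "accumulated and normalized" and is a config switch. Keypoints
whose window crosses the border or any masked-out pixel are dropped.

**Vocabulary** (`vocabulary`). A K-component Gaussian mixture (default
K = 128; K = 32 in the synthetic experiments below) is fitted by EM on
the pooled *training* descriptors, diagonal covariances with a 1e−6
variance floor (144-dimensional full covariances are not estimable from
cohorts this size), k-means++ initialization, seeded and deterministic.
EM is driven one iteration at a time so the total data log-likelihood is
recorded per iteration (monotonicity is asserted in tests); it stops at a
gain < 1e−3 or 100 iterations. Fitting is backed by
`sklearn.mixture.GaussianMixture`; densities and posteriors used by the
encoder are computed by this package in log space (log-sum-exp), so
responsibilities are a valid simplex even when raw densities underflow.
When more than 20,000 training descriptors are available the EM fit uses
a seeded uniform subsample of that size — standard bag-of-visual-words
practice; encoding always uses every keypoint.

**Weight-scaled encoding** (`encoding`). For keypoint j of image i, the
posterior over visual words P_ij and its one-hot argmax Q_ij (ties to the
lowest index) blend into the image code

    U_i = (1/J_i) Σ_j [ α·P_ij + (1 − α)·Q_ij ],  α = 0.15 by default.

α = 1 is the mean posterior, α = 0 the classical hard-assignment
histogram; small α pulls noisy boundary keypoints toward their best word
while keeping a soft trace. Because P and Q are simplex vectors, U_i sums
to 1 for any α and is exactly affine in α — both are regression-tested.
The raw weighted density p_ijk = π_k·N(V_ij | u_k, Σ_k) is not itself a
probability; we normalize over k so the "probability" reading is literal
(the unnormalized variant is available behind
`normalize_responsibilities=False`). The per-image divisor is the image's
own keypoint count J_i. Zero-keypoint images encode to the uniform 1/K
vector and are flagged as degenerate rather than aborting a run.

**Classifier** (`classifiers`). A broad learning system (BLS): 10 random
affine mapping groups of 10 nodes, 100 tanh enhancement nodes, output
weights from the ridge problem argmin ‖AW − Y‖² + ε‖W‖² with ε = 1e−3,
solved via the augmented least-squares system [A; √ε·I] (numerically
stabler than, and algebraically identical to, the normal-equations closed
form (AᵀA + εI)⁻¹AᵀY, which serves as the test oracle). A deliberately
small BLS: wide BLS variants overfit cohorts of tens of images. The
margin classifier is an RBF-kernel SVM (C = 1, γ = 1/K) exposing the
signed distance to the separating hyperplane. The ensemble blends per
class j

    Y_j = λ·softmax(Y_BLS)_j + (1 − λ)·sigmoid(dist_j),

with dist₁ the signed distance and dist₀ = −dist₁ (the symmetric
two-class reading); the two entries need not sum to 1 and the prediction
is the argmax (ties → class 0). λ defaults to 0.3 or is chosen from
{0.0, 0.1, …, 1.0} by validation accuracy with ties resolved toward the
smaller λ, i.e. toward the SVM.

**Evaluation** (`pipeline`). Repeats (default 10; 3 in the standard
synthetic experiment) of stratified 6:2:2 train/validation/test splits —
per class, ⌊n/5⌋ ids each to validation and test, remainder to training.
A 6:2:2 ratio is not a fold structure, so "cross-validation" is realized
as repeated random splits. Per repeat: vocabulary fit on training
descriptors only, all images encoded, ensemble fitted on training codes
with λ selected on validation, metrics on the untouched test split. FGR
is the positive class for recall/precision/F1. ROC uses the blended FGR
probability; AUC is the trapezoid over the threshold sweep, which equals
the Mann–Whitney pair-counting statistic with half credit for ties
(property-tested). Reported values are per-repeat plus mean (and the best
repeat, since both aggregations are of interest); reports contain no
wall-clock fields, so equal-seed runs are byte-identical.

## Synthetic data

The clinical cohort behind this method is not publicly released, so
`synthetic` generates a texture phantom with the same design: balanced
classes (default 40 + 40, mirroring the clinical cohort), a circular ROI
(radius 100 px in a 256×256 frame), 150 Gaussian-profiled primitives per
image — isotropic dots (σ = 2 px) for normal, anisotropic rods
(8 × 2 px, orientations spread ±90° around a per-image random base angle)
for FGR — on a 0.35 background with contrast 0.35, degraded by
multiplicative speckle I·(1 + 0.15·η), η ~ N(0, 1). Speckle is modeled
as multiplicative Gaussian rather than Rayleigh for seedability and
simplicity. Every level (dataset, image, noise field) derives its seed
from the master seed; regeneration is byte-identical.

What the phantom does *not* emulate: the point-spread function and
depth-dependent attenuation/shadowing of real ultrasound, anatomical
context, ROI placement variability, and the graded (rather than
dichotomous) texture differences of real placentas. Passing the
end-to-end criteria therefore demonstrates that the pipeline's machinery
is correct and that it can learn exactly the kind of texture contrast the
method targets — near-perfect accuracy on the phantom says nothing about
clinical accuracy, where the reported numbers are far lower.

## Numerical choices and degenerate inputs

- All preprocessing clips outputs to [0, 1]; constant images survive
  denoising and Gaussian filtering exactly (kernel normalization tested
  to 1e−12).
- Extremum comparison is strict; all-constant stacks yield no keypoints.
- Responsibility and density computations run in log space; far outliers
  still produce valid simplex vectors.
- GMM variance floor 1e−6; fewer descriptors than K is an error
  suggesting a smaller K.
- Hard-assignment and ensemble ties break toward the lowest index /
  smaller λ for determinism.
- Empty validation sets fall back to λ = 0.3 with a warning; single-class
  training labels are an error.
- All seeds are integers below 2³¹; per-repeat and per-image seeds are
  spawned from the master seed via `numpy.random.SeedSequence`.

## Problem sizes

The standard synthetic experiment (also what `scripts/acceptance.py`
runs) uses 80 images, K = 32, three repeats, and a 20,000-descriptor EM
subsample — chosen as the smallest configuration at which the phantom's
class contrast is comfortably learned and the whole run completes in
about a minute on one CPU. The clinical operating point from the method's
description (K = 128, α = 0.15, λ = 0.3, ≥ 10 repeats) is the library
default.

## Known limitations

- Integer keypoint positions (no sub-pixel/sub-scale refinement) and no
  edge-response suppression; elongated structures can yield chains of
  keypoints along ridges.
- Hard orientation binning makes descriptors discontinuous at bin edges;
  this follows the method's definition rather than bilinear-vote HOG.
- Binary classification only; multi-class would require generalizing the
  signed-distance term of the ensemble.
- The λ selection grid is coarse (step 0.1) by design.
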