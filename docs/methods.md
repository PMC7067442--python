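# Methods

This note documents the models, parameter choices and numerical conventions
behind `otodx`, and what the synthetic phantoms do and do not establish.

## Synthetic phantom model

Each phantom is a pure function of its `PhantomSpec` (class, ROI size,
seed, lesion count/scale, texture grain, blur sigma); identical specs give
bit-identical images.  The base layer is an elliptical pinkish-gray
"membrane" (RGB ≈ (192, 148, 138)) over a darker canal surround
(≈ (112, 84, 76)), modulated by *multiplicative* illumination noise: a
low-frequency shading field (correlation length ¼ of the short side, gain
s.d. 5.5%) plus a finer texture field (correlation length = `texture_grain`,
default 6 px, gain s.d. 4.5%).  Multiplicative shading was chosen over
additive because illumination acts as a gain — dark regions fluctuate less
in absolute terms — and because it keeps the membrane's color coordinates
from drifting across quantization bin edges under bright shading patches.

Lesions are unions of random soft-edged ellipses totalling
`lesion_scale` × ROI area (default 12%), with per-class HSV placement:
earwax blobs at hue ≈ 33° with high saturation; myringosclerosis patches at
value ≈ 0.93 and saturation ≈ 0.01; otitis media as a single dark core
(value ≈ 0.18) ringed by a red rim (hue ≈ 0°, rim width 4% of the short
side).  The bands were calibrated once so that (a) each class is separable
by color statistics and (b) the class-specific segmenters have honest
signal; they are not fitted to any numerical target.  Every lesion phantom
also emits its binary ground-truth mask (core ∪ rim for otitis).

Per-image seeds in a dataset derive from hashing (dataset seed, class,
index), so any image is reproducible independently of generation order.

**What the phantoms do not model:** specular cone-of-light reflections,
hair/shadow occlusions, camera vignetting and chroma noise, anatomical
structure (malleus, annulus), or the intra-class diversity of real disease
presentations.  Passing tests on phantoms therefore establishes the
*correctness and discriminative plumbing* of the pipeline, not clinical
accuracy; the ~99% repeated-validation accuracy reported by the acceptance
script is a separability property of the generator.

## Preprocessing

* **Blur score** — variance of the response to the 3×3 four-neighbor
  Laplacian `[[0,1,0],[1,−4,1],[0,1,0]]` on the Rec. 601 luminance channel,
  with symmetric (edge-repeating) boundary handling.  The score is
  invariant to adding a constant and scales as α² under contrast α.  The
  pass threshold is application-defined; `calibrate_blur_threshold` offers
  an Otsu split over a mixed frame set.
* **Aperture detection** — Sobel gradient magnitude, Otsu-binarized, into a
  circular Hough accumulator (1 px radius bins by default, configurable
  `radius_step`; default search radii 100–220 px for 640×480 frames, where
  the aperture fills a large fraction of the frame).  The peak is the
  normalized accumulator maximum; exact ties break toward larger radius,
  then smaller center row, then smaller column.  A peak below the score
  floor (default 0.25 of a full perimeter) raises a "no circle" error.
* **Crop** — axis-aligned `(width, height)` = (420, 380) window centered on
  the rounded circle center; out-of-frame regions are zero-padded so the
  output shape is always exact.  Coordinates are 0-based (row, col)
  internally; circle centers are reported as (x, y).

## MR8 filter bank

Kernels are built on a 49×49 support: first- and second-derivative
anisotropic Gaussians with (σ_deriv, σ_elong) ∈ {(1,3), (2,6), (4,12)} at 6
orientations, plus an isotropic Gaussian and Laplacian of Gaussian at
σ = 10.  All kernels are L1-normalized; all but the Gaussian are zero-mean.
Images are standardized to zero mean / unit variance before filtering
(reflect padding, FFT convolution with kernel-FFT caching).

Each of the six anisotropic slots collapses its 6 orientations to one
response.  Bar (second-derivative, even) kernels take the signed maximum —
their polarity (bright vs dark line) is rotation-consistent.  Edge
(first-derivative, odd) kernels take the maximum of |response|: a signed
maximum over orientations sampled on [0°, 180°) is *not* invariant under
image rotation, because orientations that wrap past 180° flip sign.  The
polarity-free maximum restores exact 90°-rotation invariance (verified in
the tests) at the cost of discarding edge polarity.  Response 8-vectors are
contrast-normalized by the Weber rule r ← r·log(1 + ‖r‖₂/0.03)/‖r‖₂.

Texton dictionaries use per-class k-means (k-means++ initialization, 4
restarts, tolerance 1e-4, ≤ 300 iterations, seeded) over pooled pixel
response vectors, subsampled to at most 10,000 per class — centroid
estimates stabilize well below that.  Centroids are concatenated class by
class; the persisted order defines the histogram bin order.  The reference
configuration (4 classes × k = 10, dictionary learned from 40 images per
class) yields 40-dim normalized histograms.  Features are computed on
luminance only.

## Block-DCT features

8×8 non-overlapping blocks, orthonormal 2-D DCT-II (DC = 8 × block mean for
a constant block; Parseval holds per block).  Eight channels are retained —
by default the lowest-frequency coefficients in JPEG zigzag order,
(u,v) ∈ {(0,0), (0,1), (1,0), (2,0), (1,1), (0,2), (0,3), (1,2)} — and the
selection is configurable, since any fixed low-frequency subset serves the
same purpose.  AC coefficients are modeled as zero-mean Laplace with
maximum-likelihood scale b = mean |x|; the DC channel is standardized
per image (subtract mean, divide by s.d. over blocks) before the same
treatment.  Quantizers are Lloyd–Max optimal for Laplace(0, b), computed by
fixed-point iteration (thresholds = code midpoints, codes = conditional
cell means, closed-form partial expectations; relative tolerance 1e-8).
Defaults: 5 levels per AC channel, 3 for DC — small alphabets keep the
quantized block space compact.  Each block's 8-vector of reconstruction
codes feeds the same texton dictionary/histogram machinery, with blocks
(not pixels) as the histogram support, since the block is the unit the
quantizer defines.

## Color coherence vector

3×3 local-mean smoothing (reflect borders, rounded to nearest integer),
uniform quantization of RGB to 27 colors (3 levels per channel, bin edges
at 85 and 170, half-open intervals with the top edge closed, index
= 9·r + 3·g + b), 8-connected component labeling, and per-color coherent
(component ≥ τ pixels) vs incoherent counts.  τ defaults to 1% of the ROI
pixel count.  The default feature is the per-color *coherent fraction*
αᵢ/max(1, αᵢ+βᵢ), length 27, honoring the 27-dimensional feature space of
the reference configuration; the classic 2N concatenation (α, β)/n, length
54, is available as `classic_54`.  Which collapse of (α, β) the reference
protocol used is not documented; the coherent fraction is an explicit
interpretation.

## Classification and evaluation

* **Splits** — stratified 80/20 with seeded per-class shuffling and
  largest-remainder rounding, so the 4×180 reference dataset gives exactly
  576/144 (144/36 per class).  Stratification is forced by those exact
  per-class counts.
* **Models** — one-vs-all SVM (RBF kernel, C = 1, gamma = "scale"; kernel
  configurable), k-NN (k = 5, Euclidean, ties toward the smaller class
  index), decision tree (Gini, unlimited depth, seeded).  SVM scores are
  one-vs-all decision values; k-NN/tree scores are class probabilities.
* **Metrics** — macro averages of the one-vs-rest binary decomposition of
  the confusion matrix.  A class with a zero denominator (absent from the
  fold) contributes 0 to the average and is flagged rather than silently
  dropped, keeping the average defined without inventing values.
* **ROC/AUC** — every element of the one-hot label indicator matrix is
  treated as one binary ground truth against its score; thresholds sweep
  the unique scores; AUC is the trapezoidal area.  Constant scores yield a
  degenerate diagonal curve (AUC 0.5) with a warning.
* **Repetitions** — repetition r uses split seed (master + r), a fresh
  model, and the validation fold; means and standard deviations are
  reported.  With a fixed held-out test set, both the per-repetition
  average and a majority-vote aggregation of the repetitions' test
  predictions are available; per-repetition averaging is the default
  because it matches the validation protocol.

The test and acceptance configurations run 10 repetitions on 180 images
per class — enough for the repeated-split mean to stabilize at the
phantoms' separability level, and comfortably sized for a desktop run.

## Suspicion highlighting

The reference system only documents its input/output pairs (ROI in,
highlighted region out), so segmentation here is the minimal method
consistent with that: per-class HSV thresholds (hue in degrees [0, 360))
with 3×3 morphological opening and closing and a minimum component area.
Defaults: earwax hue 18–52°, saturation ≥ 0.40; myringosclerosis value
≥ 0.85, saturation ≤ 0.15; otitis media core value ≤ 0.25 united with
red-hued (≤ 15° or ≥ 345°, saturation ≥ 0.45) pixels within 14 px of the
core, with a larger minimum area (1% vs 0.2% of the ROI) because the
perforation is a single large region while dark shading patches are small.
All thresholds live in the `highlight` configuration section.  Overlay
rendering draws the mask contour solidly and fills the interior at
alpha = 0.25 on a copy; the input raster is never modified, and an empty
mask sets a "no region found" flag.

## Numerical conventions and degenerate inputs

* Nearest-centroid assignment uses exact squared Euclidean distances; ties
  take the lowest centroid index.
* A constant image has zero variance; MR8 standardization guards the
  division and yields all-zero responses.
* An all-zero DCT channel raises a degenerate-channel error rather than
  fitting b = 0.
* Empty label vectors produce an all-zero confusion matrix with a warning;
  an empty matrix cannot be summarized.
* `degrade_sharpness(image, 0)` returns an identical copy; Gaussian blur
  satisfies the semigroup property up to uint8 rounding (±2 gray levels).

## Known limitations

* Phantom realism is deliberately limited (see above); absolute metric
  values on phantoms say nothing about clinical data.
* The Fig-style channel selection for the DCT descriptor and the exact CCV
  collapse are interpretations; both are configurable.
* The Hough stage assumes a single dominant bright disc; concentric or
  overlapping apertures are resolved by the documented peak/tie rule only.
* SVM hyperparameters are fixed defaults; no tuning or calibration is
  performed.
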