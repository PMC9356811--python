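# Methods

This note records the models, conventions and numerical choices behind
braintex, and what the synthetic benchmark does and does not establish.

## Image model and conventions

Images are 2-D integer grids, (row, col) indexed, 0-based, row 0 at top;
intensities lie in `0..levels-1`. Color inputs are reduced by integer
Rec. 601 luminance `(299R + 587G + 114B + 500) // 1000`; 16-bit inputs are
rescaled to 8 bits by `(v*255 + 32767) // 65535`. Quantization to G grey
levels uses uniform bins over the full representable range
(`k -> k*G // levels`), not the image's own min–max, so features are
comparable across images; min–max stretching is available behind an
explicit flag. G defaults to 8, common practice for Haralick features —
small enough that an 8-level 64×64 image populates the matrix densely,
large enough to resolve the lesion/background intensity split.

## Preprocessing

Noise suppression is Gaussian convolution (kernel truncated at 4σ,
reflective borders, default σ = 1 px), rounded back to the integer grid.
Contrast enhancement is unsharp masking,
`out = clip(x + amount·(x − blur(x, σ_s)))` with σ_s = 1, chosen among
linear high-boost filters because `amount = 0` is an exact identity.
Default order smooth → sharpen, configurable. The enhancement step doubles
as the "retouching" stage of the workflow; no inpainting is performed.

## GLCM texture features

Orientations map to offsets 0°→(0,+d), 45°→(−d,+d), 90°→(−d,0),
135°→(−d,−d) (rows grow downward, so the diagonals point up-right and
up-left); d defaults to 1. Matrices are symmetric by default (each pair
also counted reversed), matching common practice and making row and column
marginals coincide. The fifth matrix is the element-wise mean of the four
orientation matrices' probabilities.

The 14-feature vector is the classical Haralick-style set: contrast,
dissimilarity, energy (angular second moment), entropy (natural log; the
base only rescales entropies), homogeneity (inverse difference moment),
maximum probability, correlation, autocorrelation Σ a·b·p, the marginal
mean and the joint variance about it, and the four sum/difference
statistics (sum average, sum variance, sum entropy, difference entropy)
computed from the distributions of a+b and |a−b|. Marginal means and
variances are the standard probability-weighted moments of the row/column
marginals. When a marginal variance is zero (single-valued image) the
correlation is undefined and is reported as 0 with a logged warning.

## Segmentation

Binarization uses strict `intensity > t` to avoid off-by-one ambiguity.
The automatic threshold is Otsu's exhaustive between-class-variance scan
with ties broken toward the smallest threshold. Because Otsu always
returns *some* cut, a lesion-free image would otherwise binarize its
background noise into large components; `segment_tumor` therefore applies
a separability guard in automatic mode: if the Otsu effectiveness ratio
(between-class / total variance at the optimum) is below
`min_separability = 0.8`, the image is declared lesion-free. Unimodal
intensity distributions stay below ~0.75 (the uniform-density value; a
Gaussian gives ~0.64) while two separated modes approach 1, so 0.8 cleanly
divides the regimes. The guard never applies when an explicit threshold is
given.

Morphological clean-up is a closing (dilate then erode) with the 3×3
square structuring element, then hole filling, then optional
largest-component selection. Border convention: out-of-image pixels count
as background for dilation and foreground for erosion. This is the
convention under which erosion and dilation are exact complements
(`erode(m) = ¬dilate(¬m)`) and closing is extensive and idempotent on a
finite grid; with zero-padded erosion those laws fail on the border row.
Connectivity is 4-connectivity for hole filling and labeling.

The intermixed-edge detector computes vertical, horizontal and diagonal
Sobel-style gradient magnitudes, binarizes each with Otsu on its own
histogram (a constant map yields no edges), dilates each edge map with the
3×3 square, and marks pixels where all three edge types co-occur. It is
exposed as a standalone operation rather than inserted into the tumor
path, since its coupling to the mask is not otherwise defined.

## ANFIS classifier

Zero-order Takagi–Sugeno system: Gaussian memberships
`exp(−(x−c)²/(2σ²))`, product t-norm, normalized firing strengths,
strength-weighted average of per-rule class-weight vectors. Scores are
therefore convex combinations of consequents. Features are z-scored with
statistics stored in the model, so widths are in standardized units;
widths are clamped to a floor of 1e-3. Argmax ties break toward the
earlier class in (normal, benign, malignant).

Training is full-batch gradient descent with momentum,
`v ← ρ·v − η·∇E; θ ← θ + v`, on centers, widths and consequents, with the
mean per-sample sum of squared errors as the objective (class weights
default to 1). Defaults η = 0.01, ρ = 0.9: with momentum 0.9 the effective
step is ~10η, and η = 0.01 converges smoothly where η = 0.05 oscillates on
the benchmark's loss surface. The forward pass shifts log-strengths by
their per-sample maximum before exponentiating, so products of many small
memberships cannot underflow; all downstream quantities use only
scale-invariant strength ratios. Gradients are analytic and verified
against central finite differences in the tests.

Initialization is data-driven. If the full grid of membership combinations
has ≤ 256 rules, centers sit at equally spaced quantiles of each z-scored
feature (widths = half the mean spacing, floored at 0.25) and each grid
rule's consequent starts as the mean one-hot of the training points that
fire it most strongly (uniform if none) — a data-driven generalization of
indicator initialization, which is only well-defined when rules correspond
to classes. With 14 features the grid is infeasible, so one rule per class
is anchored at the class medians with indicator consequents. The hybrid
least-squares consequent step common in ANFIS implementations is not used;
all parameters follow the same momentum update.

Models serialize to a versioned JSON schema; floats round-trip exactly
(JSON `repr`), so a loaded model reproduces predictions bit-identically.

## Synthetic benchmark

The generator emulates three diagnostic classes on a 0..255 grey scale:
a smooth random-field background (mean 60, amplitude 6) everywhere;
**benign** adds one bright disc (mean 170) with a regular sinusoid
(period 8 px, amplitude 25); **malignant** adds an irregular star-shaped
region (random boundary harmonics k = 2..5, amplitudes 3–12% of the
radius) filled with ternary ±80 speckle. The speckle has a 2-pixel
correlation length so the irregular texture survives σ = 1 smoothing —
lesion heterogeneity in real images lives above single-pixel scale, and
single-pixel salt would be removed by any denoising step. Additive
Gaussian noise (σ = 5) everywhere; lesion radii span 16–25% of the image
side; default size 256×256, with 64×64 used throughout the tests and
benchmark for speed. These amplitudes order the headline features
(contrast, entropy, energy, autocorrelation) across classes:
malignant > benign > normal in mean contrast.

Everything derives from a master seed via spawned per-item seeds. Feature
clusters for classifier unit tests are three isotropic unit-variance
Gaussians at pairwise distance `separation` (equilateral placement).

What passing the benchmark shows: the pipeline's stages compose correctly,
deterministically, and can learn texture classes that differ in the
statistics the features measure. What it does not show: performance on
real MRI — the generator has no anatomy, bias fields, Rician noise,
partial-volume effects, or inter-scanner variability, and its benign/
malignant contrast gap is modest by design (the two lesion classes overlap
in feature space, so held-out accuracy varies ~0.85–1.00 across seeds).

## Benchmark protocol and sizes

Default run: 30 images per class at 64×64, stratified 70/30 split (63
train / 27 test), 200 epochs. The acceptance script uses 200 random images
(≤16×16, G ≤ 8) for the GLCM oracle, 100 random 8×8 masks for morphology
laws, 10 noise-free benign images for segmentation fidelity, 50
points/class for cluster training, and 200 points for parameter recovery.
Reports, feature tables and models are written deterministically (sorted
JSON keys, no timestamps), so repeated runs are byte-identical.

## Known limitations

- The edge-mixture operation is exploratory and not wired into the mask.
- One rule per class limits decision boundaries to what three Gaussian
  prototypes express; grid rules are exact only for few features.
- The Otsu separability guard assumes roughly constant-intensity lesions;
  very small or very dim lesions can fall below it.
- Segmentation fidelity is measured on noise-free benign discs; irregular
  malignant boundaries are recovered less exactly by a global threshold.
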