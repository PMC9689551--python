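# Methods

This note documents the models, procedures and numerical choices behind
`ricedom`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and which decisions were genuinely open.

## Problem and grading rule

A milled rice grain is graded by *skin retention*: the projected area of
residual bran plus germ divided by the grain's projected area, in percent.
Grade thresholds are < 2% (well-milled), 2–7% (reasonably well-milled) and
> 7% (substandard). The wording "between 2% and 7%" is read as inclusive at
both ends, so 2.0% and 7.0% grade as reasonably well-milled; the generator
never samples retention within ±0.2 points of a boundary, so this
convention does not affect any synthetic label.

## Synthetic scan generator

The generator emulates milled rice scanned face-down on a dark frosted
plate:

* **Silhouette** — a superellipse |u/a|ⁿ + |v/b|ⁿ ≤ 1 with exponent n ∈
  [2.2, 3.2] and aspect ratio a/b ∈ [2.2, 3.5]; grain length 95–135 px at
  the default scan scale. This mimics the capsule outline of indica rice
  without attempting photorealism.
* **Bran and germ** — 1–6 elliptical patches in grain-local coordinates,
  plus an optional germ notch at one end. A continuous "patch field"
  (maximum over patches of 1 − normalized elliptic distance) is
  thresholded at the exact in-grain pixel quantile that yields the
  requested retention, so realized retention is accurate to one pixel
  (well inside the ±0.5 percentage-point contract). Per-class retention is
  sampled from 0.2–1.8% / 2.3–6.7% / 7.5–14%.
* **Shading** — endosperm is a pale cream (grayscale base 200–225), bran a
  tan (140–165) whose BT.601 luminance stays above the binarization
  threshold, so bran never punches holes in the foreground mask. A gentle
  limb darkening (up to 15% at the silhouette edge) rounds the grain.
* **Scan composition** — background shade 15 (near-black), additive
  Gaussian noise σ = 4 gray levels, salt-and-pepper at rate 10⁻³ (to
  exercise the median filter), rejection-sampling placement with 100
  retries per grain and a minimum 4 px dilation gap between grains
  (scanned samples are physically sieved apart; touching-grain splitting
  is out of scope).

All randomness flows through one `numpy.random.Generator`; identical seeds
give bit-identical scans. Ground truth per grain: binary mask, realized
retention, grade, and the minimum-area oriented box of the mask pixels.

**What the generator does not emulate:** chalky regions, translucency,
specular highlights, double-sided bran asymmetry, scanner vignetting, and
real bran texture. Tests passing on synthetic scans therefore demonstrate
the pipeline's *mechanics* (mask extraction, box fitting, learnability of
an area-fraction cue), not field performance on real rice.

## Preprocessing

Grayscale uses ITU-R BT.601 weights (0.299/0.587/0.114) — the common
default where a method states only "grayscale transform". The median
filter replicates edges at the border; the binarization threshold is
strictly greater-than. Defaults: median kernel 3, threshold 100, opening
and closing with 3×3 square elements. A fixed threshold (rather than Otsu)
is deliberate: adaptive methods tend to split bright endosperm from darker
bran within one grain, which would fragment the mask. Threshold 100 sits
between the bran floor (~120 luminance) and the background ceiling
(~30 + noise); the generator guarantees ≥ 100 gray levels of separation.

## Segmentation

Connected components of the refined mask (8-connectivity) with area
≥ 200 px are traced to closed contours; smaller components are debris.
Contour tracing on the clean binary mask is the default foreground route —
the mask already isolates grains and needs no edge thresholds. An optional
Canny route (hysteresis thresholds 50/150, edges closed and filled) is
available via `edge_method="canny"` for scans where gradient edges are
more reliable than a global threshold; on synthetic scans both routes
find the same grains.

The minimum-area rectangle is computed by rotating calipers on the convex
hull (the optimum shares an edge direction with the hull, so only one
orientation per hull edge is tested); a 0.1° rotation-sweep oracle in the
test suite bounds the area agreement to 1%. Box angles are reported in
(−90°, 0°].

Each grain is extracted by rotating a padded *local* window about the box
center (bounded memory on large scans; bilinear interpolation,
background-shade fill), which is equivalent to rotating the whole image
per grain — per-grain rotation is the only interpretation that is
well-defined when grains have many orientations. The crop is
(short + 2·margin) × (long + 2·margin) with margin 5 px; at image borders
the crop is clamped to rows/columns covered by real pixels. Square boxes
rotate by 0 (tie-break). Crops are returned in row-major order of box
centers.

## Dataset assembly

Stratified split with val/test sizes ⌊ratio·n⌋ per class and the remainder
in train (so 5800/class at 6:2:2 gives exactly 3480/1160/1160). Flips:
"30% horizontally and vertically, respectively" is implemented as two
independent without-replacement draws of round(0.3·n) images — an image
can receive both flips. Rotation applies to *every* training image,
uniform in [35°, 135°], bilinear, background fill. Whether augmentation
replaces or appends is genuinely ambiguous; the default transforms in
place (size preserved) and `expand=True` appends. Validation and test
receive only center crop + standardization, with training-set channel
statistics (population std on [0, 1] intensities) — no leakage. Crops
smaller than the target size are padded with the background shade before
center-cropping.

## Network

The backbone (declared as a `ModelPlan`, checkable without weights via
`shape_trace`) is:

input 3×224×224 → Inception-A (64×224×224) → 3×3/2 max pool →
Residual-A1, A2 (64×112×112) → Residual-B1 (128×56×56) → Residual-A3 →
Residual-B2 (256×28×28) → Residual-A4, A5 → Inception-B (512×28×28) →
global average pool (512) → FC (3).

* Inception-A branches: 1×1(8); 1×1(12)→3×3(24); 3×3 maxpool→1×1(8);
  1×1(12)→3×3(24)→3×3(24); concatenation width 8+24+8+24 = 64.
* Inception-B branches: 1×1(64); maxpool→1×1(128);
  1×1(64)→1×7(64)→7×1(128);
  1×1(192)→1×7(192)→7×1(192)→1×7(192)→7×1(192); width 512. Two printed
  inconsistencies in the source layer table are reconciled: branch 4's
  terminal count is listed as 128 (which sums to 448, contradicting the
  stated 512 concatenation and pool width) — the default uses 192, the
  single minimal edit consistent with 512, and `literal_table=True` builds
  the 448 variant; and the pad-1 printed for Inception-A's post-pool 1×1
  convolution (which would emit 226×226 and break the concatenation) is
  corrected to 0.
* Residual blocks: identity form y = ReLU(F(x) + x) with
  F = conv3×3–BN–ReLU–conv3×3–BN; projection form
  y = ReLU(F(x) + wₛx) with stride 2 on the first main conv and a
  1×1/2 + BN shortcut. Addition precedes the final ReLU (standard ResNet
  ordering; the source is silent).
* Every convolution is followed by batch norm then ReLU unless flagged;
  weights are Kaiming-uniform (fan-in), BN γ=1 β=0.
* `width_mult` scales every kernel count (min 1); residual stage widths
  are derived as 1×/2×/4× the Inception-A concatenation width so scaled
  plans stay internally consistent (exactly 64/128/256 at full width).

The engine (`ricedom.nn`) is a compact numpy implementation — im2col
convolution with explicit col2im backward, batch norm with exact batch
statistics backward, max pool with argmax routing, softmax cross-entropy —
validated against scipy correlation and finite differences in the test
suite.

## Training

Cross-entropy; SGD (momentum 0) or Adam (β = 0.9/0.999, ε = 10⁻⁸); L2 as
coupled optimizer weight decay on convolution/FC weights only (BN
parameters and biases exempt). The schedule
`lr(e) = lr₀ · γ^⌊e/s⌋` uses integer division: "equal-interval decay"
means the rate is constant within each s-epoch interval (a fractional
exponent would decay continuously, contradicting the interval reading).
Defaults are the tuned recipe for this architecture: Adam, lr 1.9·10⁻⁴,
weight decay 2·10⁻⁴, step 15, γ = 0.085, batch 64, 100 epochs — over 100
epochs this schedule takes exactly 7 distinct rates.

**Batch-norm recalibration.** With few samples and a fast-moving
optimizer, BN running estimates lag the weights, so inference-mode
accuracy understates the model. Before each validation measurement (and
after training) the running statistics are recomputed as exact population
statistics over up to 256 training items at the current weights. This
affects only inference-mode statistics, never the gradients.

The best-validation-accuracy state is checkpointed; divergence (non-finite
loss) aborts with the epoch index; `epochs=0` returns the initial state.

## Hyperparameter search

Candidate set: optimizer ∈ {SGD, Adam}; learning rate, γ and weight decay
in [10⁻⁵, 0.1]; step size ∈ {10, 15, 20, 25, 30} (a BPNN variant swaps in
hidden ∈ {10, 12, …, 24} and step ∈ {600, …, 1400} and drops weight
decay). Ranges spanning four decades are sampled and modeled log₁₀-
uniformly; categoricals are one-hot; ordinals index-scaled. After 10
random warm-up trials a Matern-5/2 Gaussian process (normalized y,
α = 10⁻⁶) is refit each trial and expected improvement (ξ = 0.01) is
maximized over 512 random proposals. Failed trials score −∞ and the
search continues. The surrogate family, acquisition and warm-up count are
implementation decisions; the search interface hides them so a
tree-structured surrogate could be substituted.

## Desk-scale problem sizes

The full 17,400-image study regime is not reproducible here (the dataset
is unpublished); the suite instead verifies the pipeline at sizes a
workstation CPU handles:

* segmentation recovery: 20 scans × 30 grains at 1000×1400 px;
* learnability: width-0.25 backbone, 56×56 crops, 600 train / 200
  validation per class with retention pinned at 0.5/4.5/12% (cleanly
  separable by construction), Adam at 5·10⁻⁴ — chosen once as a sensible
  default for the narrow model; reaches ≥ 90% validation accuracy within
  a few epochs;
* Bayesian search: a 1-D analytic objective with a known optimum.

The architecture itself is always validated at full width via the
symbolic trace plus a single full-size forward pass.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; full-scale 224 px
  training is out of its intended scope.
* Synthetic realism is limited (see generator section); no claim is made
  about accuracy on real scans.
* Touching grains are not split (physical sieving is assumed).
* The literal-table (448-channel) variant is buildable but untrained.
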