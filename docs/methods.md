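# Methods

`headcount` implements a few-shot, density-map–based counter for cereal crop
heads (wheat spikes, maize tassels, sorghum and rice panicles). This note
records the model, its assumptions, the parameters that matter, the
numerical choices, and what the bundled synthetic data can and cannot
establish.

## Problem setting

Counting is posed as density regression: the predicted count of a query
image is the integral of a nonnegative density map `D`, trained against
ground-truth maps `D_GT` built from point annotations of head centres. The
few-shot element is that the *appearance* of the object class is not baked
into the weights: at inference time the user marks 1–k exemplar boxes
(default 3) on the image, and the network matches exemplar prototypes
against the image features. Training happens once on a base crop; novel
crops are counted with all parameters frozen (two-stage scheme).

## Model

**Encoder (frozen).** Any callable mapping an RGB image to a `C × H/4 × W/4`
feature grid can serve. The reference geometry is 512×512 images to 128×128
features. The built-in `toy` extractor is two blocks of (3×3 convolution,
ReLU, 2× average pooling) with seeded random weights — it reproduces the
stride-4 geometry and the frozen-backbone protocol at desk scale, and is
what the test-suite runs on. Wrappers for large pretrained
self-supervised ViTs plug in through the `external:<module>:<attr>` registry
key; a native patch grid that does not equal the required `H/4 × W/4` should
be bilinearly resampled by the wrapper to fit the reference geometry.

**Refined support path (frozen).** Exemplar boxes tend to include leaves
and stems, which pollutes prototypes pooled from the whole box. Each box is
therefore refined to a foreground mask (`otsu` threshold provider by
default; `boxfill` gives the unrefined baseline; a promptable segmentation
model can be plugged in as `external:`). The mask is area-averaged onto the
feature grid, binarized at “any coverage”, and the support features are
zeroed outside it. The boxed region is then adaptively average-pooled into
`C × k × k` prototypes at scales k ∈ {1, 3, 5}; pooling bins average over
mask-active cells only, and a bin with no active cell inherits the box-wide
masked mean (needed for k = 5 on small heads). Box-to-cell mapping covers
every touched cell (floor origin, ceil end) so thin panicles survive the
stride. The alternative of averaging the gated zeros into bins was
considered and rejected: it would re-introduce the background dependence the
masks exist to remove.

**Similarity comparison (MSSCM).** Query features and prototypes are
projected to a shared `C_p`-dimensional space (default 256) by a 1×1
convolution plus channel layer normalization; there are four projection
heads (query + one per scale; a config switch shares them). Each projected
prototype slides over the projected query grid as a zero-padded “same”
cross-correlation, giving raw responses `R_O^k` of shape `N × H × W`. Two
normalizations follow, with logits scaled by `1/(H_S · W_S · C_p)` (the
literal product; `logit_scale: sqrt` selects the square-root variant):

- exemplar norm `R_EN`: softmax across the N exemplars at each location —
  responsibility is distributed among prototypes, summing to 1 everywhere;
- spatial norm `R_SN`: per exemplar plane, `exp(z)/max exp(z)` over space,
  computed stably as `exp(z − max z)` (exactly equivalent in real
  arithmetic); the spatial maximum is exactly 1.

The final map is `R^k = R_EN ⊗ R_SN ∈ (0, 1]`. The scaling-inside-softmax
reading is adopted because it is the only one that keeps the exemplar norm a
proper distribution and is parallel in form to the spatial norm.

**Feature enhancement (MSFEM).** Similarity maps lose spatial structure, so
each exemplar plane is convolved with its spatially *flipped* prototype and
summed over exemplars — every similarity value stamps a prototype-shaped
contribution at its location, returning to feature space
(`f_R^k`, `C × H × W`). Reconstruction uses the unmapped, backbone-space
prototypes — the only channel-consistent option, since the result is later
added residually to the query features; the projection heads act only inside
the similarity computation. Each scale then receives spatial attention
(`sigmoid(7×7 conv over [channel-mean; channel-max]) ⊗ f_R^k`). The scales
are concatenated (3C channels) and fused by strip-convolution attention: a
5×5 depthwise base; three depthwise branch pairs 1×7/7×1, 1×11/11×1,
1×21/21×1 applied to the base; a 1×1 convolution of (base + Σ branches)
forming a multiplicative attention over the concatenation; and a 1×1
reduction back to C channels. This is the canonical strip-attention wiring;
the kernel sizes are fixed by the design, the connections between them are
our choice, recorded here. Finally
`f_P = LayerNorm(f_Q + h(f_C'))` with `h` two 3×3 convolutions and one ReLU
between. The whole block iterates `n_iterations` times (default 2 — enough
to exercise the feedback path at desk scale), feeding `f_P` back as the
query.

**Decoder.** Three (3×3 convolution, nonlinearity) blocks with channel plan
C → C/2 → C/4 → 1 and 2× bilinear upsampling after the first two blocks
(total ×4, back to image resolution). Hidden activations are ReLU. The
*output* nonlinearity is a softplus with its bias initialized to −6:
density targets are zero on the vast majority of pixels, and with a ReLU
output the training signal can die permanently once the output layer's
pre-activations go all-negative (we observed exactly this collapse — the
loss froze bit-for-bit). Softplus is nonnegative everywhere but has no
zero-gradient region, and the negative prior bias starts the predicted mass
near a typical object count instead of proportional to the image area, the
usual bias initialization for sparse targets. The depth/channel plan is a design
choice of this package and is config-overridable.

**Ground truth and loss.** Each annotated centre contributes a discrete
Gaussian kernel with geometry-adaptive width: σ_i = 0.3 × (mean distance to
the 3 nearest other points), clamped to [1, 15] px, σ = 4 px when fewer than
4 points exist. Kernels are truncated at 4σ and renormalized to unit mass,
so Σ D_GT equals the count *exactly*, border points included — the
evaluation identity `count = Σ density` depends on this. The loss is
`(1/M) Σ ‖D − D_GT‖²` over the mini-batch (M = 1 by default; larger M is
implemented as accumulation over the batch before the optimizer step).
Predicted counts are the raw real-valued density sums; no rounding.

**Metrics.** MAE, RMSE, counting accuracy `100·(1 − mean(|C−C_GT|/C_GT))`
(unclamped, can be negative), and R². Zero-truth images raise an explicit
error rather than being skipped — relative error is undefined there, and the
evaluation protocol excludes nearly-empty images anyway.

## Training protocol

Stage 1 updates only the projection heads, the enhancement block, and the
decoder, with Adam; reference settings are learning rate 2×10⁻⁵ decayed by
0.25 every 80 of 200 epochs, batch size 1. The encoder and the whole
support path are frozen in both stages, enforced by SHA-256 parameter
checksums asserted in the tests. Stage 2 is pure inference; a checksum
before/after any number of calls is identical. All tensors are float64 and
all randomness flows from explicit seeds; reruns are bit-stable on a fixed
platform.

Because no deep-learning framework is part of the dependency set, the
package carries a minimal reverse-mode autodiff core (`_autograd.py`):
tensors over numpy arrays with the operator set this model needs
(broadcast arithmetic, matmul, reductions with max/mean, im2col-based
convolution, shift-and-accumulate depthwise convolution, layer norm,
softmax, sigmoid/softplus/ReLU, bilinear up-sampling as fixed interpolation
matrices). Every operator's gradient is finite-difference-checked and every
forward operator is checked against an independent loop-based oracle in the
test suite.

## Synthetic data

`fixtures.generate_field` renders golden elliptical head-like blobs (major
semiaxis 3–6 px at 64×64 by default, eccentricity 0.3–0.8, random
orientation, optional overlap) over a cluttered background of low-frequency
colour noise plus dark leaf/stem stripes whose density is `clutter_level`.
It emits exact centre points, tight exemplar boxes with a 2-px margin
(deliberately containing background, so mask refinement is testable), and
the exact rendered foreground mask per box. Identical spec + seed is
byte-identical.

What it does *not* emulate: photorealistic texture, illumination and
altitude variation, perspective, within-image scale gradients, severe
occlusion chains, or the appearance gap between crop species. Passing the
end-to-end study therefore shows that the pipeline's machinery — prototype
matching, similarity normalization, enhancement, decoding, training
dynamics — can recover counts from images with cluttered backgrounds; it
does not certify accuracy on real field imagery, which additionally depends
on a strong pretrained encoder.

## Verification study sizes

The end-to-end recovery study (also what `scripts/acceptance.py` reruns)
uses the tiny configuration — 64×64 images, 16×16 features, 32 backbone and
32 projected channels, toy extractor, boxfill masks, one enhancement
iteration — with 200 generated fields of 5–15 heads split 150 train / 50
test, 30 epochs, Adam at its canonical 1e-3 default with the decay interval
scaled to keep the 80-of-200 ratio (12 of 30). These sizes were chosen once
as a single-CPU-scale study; the success criterion is relative (test MAE
below half the constant train-mean predictor's MAE, R² above 0.5), not a
point value. At seed 1 this yields test MAE ≈ 1.24 against a baseline of
≈ 2.55 and R² ≈ 0.69.

## Known limitations

- The toy extractor is a random frozen CNN; it provides texture/colour
  separability, not semantics. Real deployments should plug a pretrained
  ViT through the extractor contract.
- Bilinear resampling of arbitrary input sizes to the model size preserves
  density mass by construction but was not validated against tiling-based
  alternatives for very large aerial images (a crop-tiling option is the
  natural extension).
- The threshold mask provider assumes the head occupies the centre of its
  exemplar box and is separable in intensity; it degrades to the box
  interior (with a warning) rather than failing.
- Single-image batches dominate; the autodiff core is single-threaded and
  CPU-bound, so training beyond desk scale is out of scope.
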