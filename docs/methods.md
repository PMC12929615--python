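# Methods

## Model

`patchmil` implements a deliberately constrained multiple-instance
classifier for square grayscale images. An image of side `S` is tiled into
`P × P` non-overlapping patches of side `p = S / P`. One shared encoder
`f_θ` maps each patch `x_i` (no positional input, no communication between
patches) to a vector of per-label logits `z_i ∈ R^C`. The image-level
logits are the fixed arithmetic mean

    Z = (1 / P²) · Σ_i z_i,        ŷ = σ(Z)   (elementwise sigmoid),

with the sigmoid applied strictly **after** averaging, so no squashing
limits any single patch's influence on the global logit. Because the
aggregation is a fixed mean rather than learned attention, the quantity
`z_i / P²` is the *exact* additive contribution of patch `i` to the
decision — the logit field is the explanation, and painting it over the
image (block-constant) is a saliency map that requires no gradient-based
post-hoc attribution. Scaled patch logits `ẑ_i = ŷ ⊙ z_i` fold a limited
amount of global context into the attribution while preserving each
value's sign (σ > 0).

Setting `p = S` degenerates the model to an ordinary image-level
classifier: the mean over one patch is the identity, so the forward pass
equals the bare encoder plus sigmoid, bit-for-bit on the same arithmetic
path. This reduction is asserted in the tests.

Assumptions inherited from the architecture: evidence for a label must be
recognizable from `p × p` context alone; pathologies requiring integration
of spatially distant cues are outside the model family's reach (a
deliberate trade of capacity for interpretability).

## Shift-smoothed saliency

A single tiling yields a block-constant map. To reduce block artifacts we
average over shifted tilings: for every offset `(dy, dx) ∈
{0, o, 2o, …, p−o}²` the patch grid is displaced relative to the image
(equivalently, the image content is shifted down-right on a zero-padded
canvas that grows by one patch row/column on the shifted axes, so nothing
is clipped), classified in one forward pass, painted block-constant,
cropped back to original coordinates, and the `(p/o)²` aligned maps are
averaged pixelwise.

Design choices, fixed for bit-reproducibility:

- Offsets are non-negative; content moves toward the bottom-right and the
  exposed top-left border is zero-padded.
- Every pixel is covered by exactly one patch in each shifted tiling, so
  the smoothed map is a plain average of `(p/o)²` values everywhere; an
  input-independent encoder therefore produces a spatially constant map.
  Border patches of shifted tilings partially cover zero padding; no
  border renormalization is applied.
- `o = p` reproduces the single block map exactly (one forward pass);
  `o = 1` costs `p²` forward passes. Forward-pass count is exactly
  `(p/o)²` per image per source.
- For the scaled source, `ŷ` is recomputed from each shifted tiling's own
  forward pass, since `ẑ` is defined per forward pass.
- The raw block map (`o = p`) conserves the decision: its pixel mean
  equals `Z[label]` up to the accumulation order of the mean.

Overlay rendering blends the grayscale image with a diverging tint — red
for positive (evidence for the label), blue for negative, alpha
proportional to |value| — with the color scale symmetric about zero and
anchored at the per-image max |value|, so zero stays visually neutral and
maps from different images are each shown at full dynamic range (scales
are per-image, not comparable across images).

## Localization evaluation

The protocol evaluates each (image, pathology) case:

- **Hit rate (pointing game).** The saliency argmax pixel; a hit iff it
  lies inside the expert mask. Ties at the maximum are resolved toward the
  smallest row-major pixel index — ties are common for block-constant
  maps, and determinism is required. A permissive mode (hit if *any*
  maximal pixel is inside) exists but is off by default. Cases without a
  non-empty ground-truth mask are excluded from the hit-rate N.
- **mIoU over TP/FP/FN.** Maps are binarized by a strict per-label
  threshold (`value > t`; a threshold above the global max yields an empty
  mask). A case is TP (positive label, non-empty predicted mask), FP
  (negative label, non-empty mask), FN (positive label, empty mask), TN
  (negative, empty). IoU is computed for TPs; FPs and FNs contribute 0
  (overlap with an empty set); TNs are excluded; the mean runs over all
  included cases. A TP-only variant averages TPs alone; it can only exceed
  the full variant.
- **Threshold tuning.** One threshold per label maximizes validation
  mIoU(TP/FP/FN) over a candidate grid: `grid_size` quantiles (default
  100) of the pooled validation saliency values for that label,
  deduplicated, plus a `−∞` sentinel (the all-ones mask). Quantile grids
  adapt to any saliency scale; ties break toward the larger threshold.
  Thresholds are applied to raw map values, not per-image-normalized ones.
- **Classification.** AUROC (Mann–Whitney normalization; ties half), and
  sensitivity / specificity / accuracy at the per-label Youden threshold
  (maximizing sensitivity + specificity on the validation split, rule
  `score > t`, ties toward the larger threshold).
- **Uncertainty.** Percentile bootstrap: resample cases with replacement
  (same N), recompute, take 2.5/97.5 percentiles. Percentile (not BCa)
  intervals keep the procedure simple and exactly seed-reproducible;
  resamples on which a metric is undefined (e.g. a single-class draw) are
  skipped and counted. Default 100 000 resamples; desk-scale runs use
  fewer via the `resamples` argument.

## Training

Training uses only image-level labels. Each step: augment a batch of `B`
images (default 16; effective patch batch `B·P²`), forward all patches
through the shared encoder, average to `Z`, apply multi-label binary
cross-entropy in the logit-stable form on the **global** output only, and
backpropagate — every patch receives logit gradient `(ŷ − y)/(B·C·P²)`.
There are no per-patch auxiliary losses; when all patches are identical
the parameter gradients from the patch pipeline equal those of plain
image-level training (asserted in the tests).

Optimization is AdamW (decoupled weight decay) under a one-cycle schedule:
linear rise to the peak learning rate over the first 5% of steps (the peak
default is 1e-4), then cosine annealing. Augmentation: random square crop
covering 50–100% of the area resized back to `S` (bilinear), rotation
uniform in ±5° (bilinear, zero fill), brightness factor uniform in
[0.7, 1.3], clipped to [0, 1]. Degenerate draws short-circuit to exact
identities. Betas (0.9, 0.999) and weight decay are exposed in the config.
All randomness (shuffling, augmentation, initialization) flows from seeded
`numpy` generators; equal seeds reproduce equal loss curves to 1e-5.

Because the package targets CPU-scale experiments, the encoder stack is a
compact, fully seeded numpy implementation: im2col convolution, ReLU,
global average+max pooling, linear layers, reverse-mode gradients checked
against central differences. The bundled `TinyCNN` (two stride-2 3×3 conv
blocks of 12 and 24 channels → concatenated global average and max
pooling → a linear C-logit head, inputs centered to [−1, 1]) is the
default trainable encoder; `PatchMLP` is a simpler baseline. The max-pool half of the
pooling is load-bearing: lesion evidence inside a patch is often a thin
edge arc whose averaged response is diluted, while its maximum response
survives. Any object honoring the encoder contract (batch of `(N, p, p)`
patches → `(N, C)` logits, positionless, order-independent) can be
substituted — including large pretrained backbones when a GPU stack is
available.

Desk-scale runs in the tests and the acceptance script train `TinyCNN`
from random init with peak learning rates of 1e-2 to 2e-2, weight decay
1e-4, and 12–40 epochs depending on task difficulty; a small from-scratch
network needs a far larger step size than a large pretrained backbone,
while rates much above 2e-2 make this architecture oscillate. Logit
magnitudes grow slowly by design — with sparse evidence a single
informative patch must reach a logit of order `P²` before the *global*
cross-entropy moves far from its prior value, so ranking quality (AUROC)
and localization saturate long before the loss looks converged.

## Synthetic phantoms

The generator emulates a weakly labeled radiograph cohort at `S = 128`
with `C = 3` labels: a smooth bright "thorax" ellipse with a soft sigmoid
edge over a dark field, a gentle vertical intensity gradient, and additive
Gaussian noise (σ = 0.03, clipped into [0.02, 0.98] before lesions).
Per-label lesion families:

| label          | shape                | size (px)          | contrast Δ | prevalence |
|----------------|----------------------|--------------------|-----------|------------|
| focal_opacity  | disk                 | radius 12–20       | +0.28     | 0.35       |
| linear_device  | bar (half-thickness 4) | half-length 16–26 | +0.30     | 0.35       |
| lucency        | ellipse (aspect 0.65–0.9) | semi-major 13–19 | −0.30   | 0.35       |

Labels are independent Bernoulli draws; each present label places its
lesion(s) uniformly at random (fully inside the border), with rejection
sampling so that masks of different lesions never overlap — overlapping
opposite-contrast lesions could cancel pixelwise and void the mask
guarantee. The exact rasterized support of every lesion is recorded as a
binary mask. Lesion contrast (≈ 0.3) is an order of magnitude above the
noise, making the recovery task hard but solvable for a small encoder;
mean mask area is a few percent of the image, so the hit-rate chance floor
(the probability that a random argmax lands inside the mask, which equals
the mean mask area fraction) is low.

The recovery experiments evaluate localization on shift-smoothed raw maps
with offset `o = 2`: the explanation resolution must be finer than the
thinnest structure to be pointed at, and the bar lesions are only 8 px
thick against a 16 px patch side — at `o = p` a whole block is painted
with one value and the row-major argmax convention lands on block corners,
which thin masks rarely contain. The `o` hyperparameter is exactly this
resolution/compute dial: `(p/o)²` forward passes per image.

Counterfactual pairs — identical background, noise and geometry, with one
label's lesions (or all) toggled off — are generated from the same RNG
substream. They give exact oracle bounds: the per-label
`|image − counterfactual|` map has hit rate 1.0 by construction (every
mask pixel differs between the pair), and a uniform-random map hits at the
chance floor. Trained models are judged between these bounds.

The optional shortcut mode stamps a bright square marker (intensity set
exactly) in a configurable corner with `P(marker | label=1) = ρ` and
`P(marker | label=0) = 1 − ρ`: at ρ = 1 the marker is a perfect label
proxy (the laterality-marker confound), at ρ = 0.5 it is independent of
the label. In the shortcut-exposure experiment the lesion contrast is set
to 0 — the *only* signal is the marker — and the trained model's saliency
argmax is expected to expose the cheat by landing in the marker's patch.

What the phantoms do **not** emulate: anatomical texture (ribs,
vasculature), projection physics, scanner/vendor post-processing, label
noise, inter-annotator mask variability, and global (non-localized)
confounds. Passing the synthetic recovery experiments therefore
demonstrates that the architecture, training loop and evaluation protocol
are correct and that localized signal is recoverable and attributable —
not that any particular clinical performance level would be reached on
real radiographs.

## Numerical choices and degenerate inputs

- Sigmoid uses the two-branch stable form; no overflow at |Z| ~ 1000.
- The patch mean uses numpy's pairwise summation; the decomposition
  identity is asserted to 1e-5, far above its error.
- Binary cross-entropy uses the `max(Z,0) − Z·y + log1p(exp(−|Z|))` form.
- Non-divisible `S/p` is a hard error (never silent padding); non-finite
  logits name the offending patch index; an empty ground-truth mask makes
  the hit indicator an error, not a miss; IoU of two empty masks is an
  error routed through the TP/FP/FN/TN categorization.
- Run-length masks: column-major runs, zero-run first (empty mask `[S·S]`,
  full mask `[0, S·S]`); PNG masks are strict {0, 255}.
- File-backed cohorts quantize images to 8-bit PNG; training on reloaded
  cohorts therefore sees ≤ 1/510 quantization error, irrelevant at the
  lesion contrasts used.

## Known limitations

- The numpy training stack is single-threaded CPU code meant for
  method-level experiments, not large-scale training; the encoder contract
  is where a GPU backbone would plug in.
- One-cycle annealing shape (cosine) and AdamW betas/weight-decay defaults
  are conventional choices, config-exposed.
- Bootstrap intervals are percentile, not bias-corrected; for very small N
  or heavily skipped resamples they can be short.
- The saliency evaluation thresholds raw map values; per-image
  normalization before thresholding is a documented alternative that would
  change tuned thresholds but not the hit rate (argmax is
  normalization-invariant for positive scalings).
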