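# Methods

## Problem and model

`afnnet` segments cell nuclei in microscopy images: given an RGB tile, it
predicts a per-pixel foreground probability for nucleus versus background.
Nucleus images are dominated by small objects, touching or overlapping
instances, and low-contrast boundaries, so the architecture and the
training objective are both built around boundary fidelity and
small-object sensitivity.

The network is a five-level U-Net-family encoder–decoder:

* **Encoder levels 1–2 — DSCOM blocks.**  Each Double-Stage Channel
  Optimization Module runs two stages of *standard conv → depthwise conv →
  batch norm → ReLU*.  The standard convolution changes the channel count
  (C_in → C_out in stage 1, C_out → C_out in stage 2); the depthwise
  convolution refines each channel independently at low parameter cost.
  These blocks operate at the two highest resolutions, where the detail
  relevant to small nuclei lives.
* **Encoder levels 3–5 — transformer stages.**  A 3×3 stride-2
  convolution embeds the feature map into tokens (one per spatial
  position), followed by pre-norm blocks of multi-head self-attention
  (4 heads) and an MLP (expansion 4).  Default depths are 1/2/2 for
  levels 3/4/5.
* **Skip fusion — WFEU.**  At each of the four decoder levels, the
  encoder feature and the upsampled decoder feature are concatenated
  (encoder channels first) and passed through:
  * **WFIU** — a sigmoid-gated interaction
    `x3 = σ(W1∗x + b1) ⊙ GELU(W2∗x + b2)`: the sigmoid branch is a
    learned spatial/channel weight map, the GELU branch a nonlinear
    transform; the product suppresses background features and keeps the
    salient ones;
  * **FEU** — `out = GELU(W3∗x3 + b3) + (W4∗x + b4)` where `W4` is a 1×1
    convolution aligning the concatenated input to the output width,
    making the fusion residual.
* **Decoder.**  Bilinear 2× upsampling followed by a 3×3 conv sets the
  width for each level; after fusion a conv+BN+ReLU block refines.  A 1×1
  convolution head emits one logit channel at input resolution; all
  losses consume logits.

Default widths (16, 32, 128, 160, 256) put the model at ≈6.0 M trainable
parameters.  A test-scale configuration (`ModelConfig.tiny()`:
widths 4/8/16/16/16, depth-1 transformers, ≈57 k parameters) is used by
the test suite and the scaled-down learning checks.

## Training objective

The loss is a weighted sum of three terms,

    L = α·BCE + β·Dice + γ·Boundary,   α = √2/2, β = γ = 1 + √2/2,

with ξ = 1e-6 smoothing the Dice ratio.  BCE drives per-pixel
classification; the soft Dice term counteracts foreground/background
imbalance; the boundary term integrates ‖∇σ(P)‖₂ against the Euclidean
distance transform of the ground-truth mask boundary, charging predicted
probability edges in proportion to how far they sit from the true
boundary.  Damping α below 1 while keeping β, γ above 1 shifts emphasis
toward region overlap and boundary placement.

**A note on the weight rendering.**  The source describing this loss
prints the coefficients in a typographically ambiguous form that reads as
"22 : 1+22 : 1+22".  We interpret them as α = √2/2 ≈ 0.707 and
β = γ = 1 + √2/2 ≈ 1.707: the accompanying prose says the first
coefficient *moderately reduces* the BCE contribution (so α < 1) while
the other two are *larger values*.  The weights are plain config values
(`loss.alpha/beta/gamma`), so any other reading is a one-line change.

### Discrete conventions of the boundary term

The continuum definition (boundary = label-change points, distance =
infimum over the boundary set) needs a discretization; ours is:

* **Inner boundary, 4-connectivity.**  A foreground pixel is boundary iff
  an in-image 4-neighbor is background.  Pixels outside the image
  contribute no label change, so an all-foreground mask has an empty
  boundary.  This keeps B_G a subset of the foreground.
* **Empty boundary ⇒ zero distance map ⇒ zero loss.**  The infimum over
  an empty set is undefined; zero avoids exploding loss on empty tiles
  during patch training.
* **Gradient on probabilities, not logits.**  σ(P) bounds the gradient
  field to a scale commensurate with BCE/Dice.  Scheme: forward
  differences with replicate padding at the last row/column (the
  difference there is exactly zero); central differences and Sobel are
  available via `loss.gradient_scheme`.
* **Mean, not sum, over pixels.**  Matches BCE's 1/|Ω| normalization and
  keeps the term independent of tile size.
* **Distances in pixel units** by default; `loss.normalize_distance`
  divides by the image diagonal.
* The predicted boundary set B_P (threshold + inner boundary) is exposed
  for diagnostics only; the loss itself uses the gradient field.

BCE is computed in the logit domain as `G·softplus(−P) + (1−G)·softplus(P)`,
which is exact and finite for arbitrarily large |P|.  The distance map is
a constant with respect to P, so the boundary term's gradient flows only
through the gradient-magnitude factor; the magnitude uses a zero
subgradient at exactly-zero gradient vectors.

## Numerical engine

No GPU framework is used: `afnnet.nn` is a compact reverse-mode
autodifferentiation engine on numpy arrays (elementwise ops with
broadcasting, batched matmul, grouped/depthwise 2-D convolution, max
pooling, bilinear upsampling, batch/layer norm, attention).  Stride-1
convolutions are evaluated as one BLAS call per kernel tap;
strided ones through an im2col matrix.  Training runs in float32; the
finite-difference gradient checks run the same code in float64.
Initialization is Kaiming-uniform for convolutions and truncated normal
(std 0.02) for transformer weights, drawn from a generator seeded by
`ModelConfig.seed`, so a config fully determines the initial parameters.

## Optimization protocol

Defaults follow the protocol the architecture was designed around: AdamW
(β₁ = 0.9 — the protocol's "momentum 0.9" — β₂ = 0.999, decoupled weight
decay 1e-2), initial learning rate 1e-3 cosine-annealed per epoch to
1e-5, batch size 8, 200 epochs, inputs resized to 256×256.  A
`monuseg`-style preset (plain Adam, 224×224, batch 4, 300 epochs) is
provided.  Augmentation applies one sampled similarity transform per
sample — rotation ±90°, horizontal/vertical flips, isotropic scale in
[0.8, 1.25] — identically to image (bilinear) and mask (nearest-neighbor,
so masks stay binary), then resizes and standardizes intensities with
per-channel statistics of the training split.  Evaluation applies resize
+ normalization only and thresholds σ(P) at 0.5 (configurable).

Train/validation membership is a pure function of (seed, sample id) — a
hashed 80/20 split — so adding or removing samples never reshuffles the
rest.  Best-checkpoint selection is by validation Dice, tie-broken toward
the earlier epoch.  With a fixed seed, runs are bit-reproducible: the
augmentation stream, batch order, initialization and split all derive
from it.

## Metrics

IoU, Dice, Precision, Recall and Specificity from pixel confusion counts
with foreground positive.  Degenerate ratios (e.g. empty prediction vs
empty truth) resolve to 1.0, consistent with the smoothed-Dice
convention.  Aggregation over an evaluation set is the mean of per-image
scores by default; a pixel-pooled mode is available since published
nucleus benchmarks do not always state which they use.

## Synthetic data

The generator emulates fluorescence-like nucleus tiles: n ~ U[n_min,
n_max] rotated ellipses (radius 2–10 px, axis ratio 0.5–1.0) rasterized
by pixel-center inclusion, painted at intensities 0.55–0.95 over a
textured background (0.05–0.25 plus a smooth random field), with additive
Gaussian noise (sd 0.03) and clipping to [0, 1].  Masks are exact by
construction, per-nucleus instance masks included; overlap is allowed by
default (touching nuclei are a hard regime worth exercising) and can be
forbidden, in which case placement is by rejection sampling with a
bounded retry budget.  Randomness is counter-based — sample `index` under
spec `seed` is an independent stream — so any subset regenerates
bit-identically in any order, and written datasets (Bowl-2018 stage-1
layout, 8-bit PNG) are byte-identical across runs.

What the generator does *not* model: H&E staining variation, chromatin
texture inside nuclei, out-of-focus blur, imaging artifacts, and the
tissue-type diversity of real benchmarks.  Passing the learning checks on
this data shows the architecture, loss, gradients and training loop are
correctly wired and can fit nucleus-like geometry; it does not certify
benchmark-level accuracy on real microscopy data.

## Scaled-down verification runs

The verification suite sizes its computations for a single CPU:

* single-batch overfit: 8 synthetic 64×64 tiles, tiny model, ≤300 steps,
  AdamW at lr 3e-3 with weight decay 0 (memorization is the goal of this
  check, so decay is off and the rate suits a few-hundred-step budget);
  expected training Dice ≥ 0.95;
* reduced training: 200 synthetic 64×64 tiles, tiny model, 20 epochs,
  lr 3e-3 annealed to 1e-4, rotation range ±45°; expected held-out Dice
  ≥ 0.85 (typically ≈0.92);
* all oracle comparisons (distance transform, scalar block references,
  metric identities) run on 5–16 px fixtures or ≤1000-sample sweeps.

## Known limitations

* Global self-attention is quadratic in token count; at 256×256 the
  level-3 stage attends over 4096 tokens, so inference there uses small
  micro-batches and training at full resolution is slow on CPU.  The
  engine is sized for correctness and small-scale experiments, not for
  reproducing GPU-scale benchmark training.
* Only binary (single-class) segmentation heads are provided.
* MoNuSeg-style data is supported only as pre-converted image+mask
  directories; polygon annotation parsing is out of scope.
* The published parameter/compute figures for this architecture family
  depend on unpublished width/depth choices; the defaults here land in
  the same single-digit-million parameter range but are not an exact
  match.
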