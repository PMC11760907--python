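# Methods

## Problem and model

Retinal blood vessels in fundus photographs are thin, branching, low-contrast
curvilinear structures; segmenting them pixel-by-pixel is the canonical
benchmark task of the DRIVE and STARE datasets.  `vesselseg` frames the task
as binary pixel classification: an H×W×3 image x in [0,1] is mapped to a
probability map P(x) in (0,1)^{H×W}, trained with pixel-wise binary
cross-entropy

    BCE(y, ŷ) = −(1/N) Σ_i [ y_i log ŷ_i + (1−y_i) log(1−ŷ_i) ]

against the binary annotation y, and thresholded at 0.5 for the confusion
metrics.

Four base networks share one forward contract (same output size as input,
sigmoid head, eval-mode determinism):

* **unet** — per encoder level two 3×3 conv + ReLU then 2×2 max-pool with
  channel doubling from `base_channels`; a two-conv bottleneck at
  `base_channels·2^depth`; a mirrored decoder (transposed-conv upsampling,
  skip concatenation from the matching encoder level, two 3×3 conv + ReLU);
  1×1 conv + sigmoid head.  No batch norm, matching the classic layout.
* **resnet50_seg** — canonical ResNet50 encoder (7×7/2 stem, max-pool, then
  bottleneck residual stages of 3/4/6/3 blocks with batch norm and projection
  shortcuts), a pyramid module of parallel 3×3 convolutions at dilation rates
  (1, 2, 4) fused by a 1×1 conv, and a five-step upsampling decoder taking
  skip connections from the stem and the first three stages.
* **unet_resnet_backbone** — the same ResNet50 encoder tapped at strides
  2/4/8/16/32, feeding a U-Net-style double-conv decoder (4 skip
  connections) plus a final skip-free upsampling level back to full
  resolution.
* **ctu_net** — the U-Net with its bottleneck convolutions replaced by a
  transformer: the deepest map is projected by a 1×1 conv to
  `base_channels·2^depth` channels, flattened to one token per spatial
  position, given learned positional embeddings, passed through pre-norm
  blocks of multi-head self-attention and a ReLU MLP (ratio 4), layer-normed
  and reshaped back.  Defaults: 2 blocks, 4 heads — the smallest standard
  configuration in which every token attends to every other.

**Stacking ensemble.**  With K trained bases frozen, their probability maps
are concatenated channel-wise, Z(x) = [P_1(x) … P_K(x)], and a meta-model
g — a 3×3 convolution with 64 filters and ReLU followed by a 1×1 convolution
and sigmoid — is trained with the same pixel-wise BCE to produce
P_final(x) = g(Z(x)).  The hidden 3×3 convolution carries no bias term
(2 304 weights; the 1×1 head has 64 weights + 1 bias, 2 369 parameters in
total at K = 4): before a ReLU acting on non-negative probability inputs the
bias adds nothing the 1×1 head's bias cannot express.  Meta inputs are
post-sigmoid probabilities, not logits, and the channel order
(unet, resnet50_seg, ctu_net, unet_resnet_backbone) is recorded in every
checkpoint.

The meta-model is fit on base predictions over the *training* split.  When
the bases have memorised the training set their training-split predictions
overstate their reliability and the meta-model can inherit that bias; an
out-of-fold stacking scheme would remove it at the cost of retraining every
base per fold, and is deliberately not implemented.  The risk is mitigated
here by checkpointing the meta-model on held-out validation loss.

## Numerical engine

No deep-learning framework is used: `vesselseg.nn` is a compact reverse-mode
automatic-differentiation engine over numpy float32 arrays.  Convolutions are
computed by strided-slice im2col and a single matmul per layer; transposed
convolutions by the exact adjoint scatter; max-pooling is non-overlapping
(kernel = stride = 2; the ResNet stem pool uses this too — on the even input
sizes these networks require, it halves resolution exactly as the canonical
3×3/2 pool does).  Batch norm keeps running statistics with
momentum 0.1 and uses them in eval mode, which is what makes inference
deterministic.  Every gradient is verified against central finite differences
in the test suite, and conv/transposed-conv against scipy correlation and the
adjoint identity.

Weight init is He-normal with an explicit `numpy.random.Generator` per model,
consumed in fixed construction order — two builds from one seed are
bit-identical.  Adam uses (β₁, β₂) = (0.9, 0.999), ε = 1e-8.  BCE is computed
from logits in the numerically stable max-form during training; the metric
suite clips probabilities to [1e-7, 1−1e-7].

## Training protocol

Defaults follow the reference protocol: Adam at learning rate 0.01, 500
epochs, batch size 32, `steps_per_epoch = max(1, floor(n_train/32))` (so the
20-image DRIVE training set takes one step per epoch), validation at the end
of every epoch, and a checkpoint of the parameters at the first epoch
attaining the minimum validation BCE.  The validation set equals the test
set — the protocol defines no third split — which is a leakage caveat the
API lets you avoid by passing an explicit `val` set.  Augmentation (train
only): rotations up to ±15°, independent axis shifts up to ±10%, zoom
uniform in [0.8, 1.2] (the conventional symmetric reading of "up to 20%"),
horizontal flip with probability 0.5; image warped bilinearly, mask
nearest-neighbour and re-binarised, out-of-bounds filled with 0 to match the
dark field-of-view exterior.

Seeding: one experiment seed drives three independent derived streams
(parameter init, batch sampling, augmentation draws) via
`numpy.random.SeedSequence`, making an experiment rerun byte-identical on one
device.  A non-finite loss raises immediately, naming the epoch and step.

## Synthetic data generator

The generator reproduces the statistics that make the task hard, not the
appearance of a clinical photograph.  A vessel tree is grown by seeded
recursive random walks: each root starts on the field-of-view boundary
heading inward, advances `step_len` pixels per depth level with Gaussian
heading jitter (sd 0.3 rad), branches with probability 0.4 at ±(20–50°), and
children shrink by a width factor 0.75 down from a root caliber of 5 px (at
256×256; geometry scales with image size) — giving the thick-trunk/thin-twig
caliber hierarchy of real vasculature.  Rendering places the blurred tree as
a dark structure (contrast 0.45) on a bright background (level 0.75) with a
linear illumination gradient (amplitude 0.15), Gaussian sensor noise
(sd 0.03), a red-dominant tint, and zeros outside the circular FOV (radius
fraction 0.95).  Default trees cover roughly 5–15% of the frame, the sparse
regime of real annotations.

What it does *not* contain: optic disc, fovea, lesions, inter-image camera
variation, annotator disagreement, or JPEG-like artefacts.  Passing tests on
this data demonstrates that the architectures, losses, training loop and
ensemble logic are correct and that vessels of decreasing caliber are
learnable at low contrast — not that clinical-grade accuracy transfers to
real fundus images.

## Desk-scale study sizes

All shipped experiments run on one CPU core.  The synthetic benchmark used
by the tests and the reproduction script trains all four architectures at
1/8 width (`base_channels=8`) on 64×64 images, 40 training / 10 test
samples, 30 epochs of 5 batches of 8.  The width-reduced plain U-Net
variants are unstable at the protocol's 0.01 learning rate, so they train at
1e-3; the batch-normed ResNet variants use 3e-3; the meta-model, a two-layer
convolutional fuser, keeps the protocol's 0.01.  Under these conditions the
fused model's test F1 matches or exceeds the best single base in most seeded
runs, the qualitative finding the full-scale study reports.

## Evaluation conventions

Metrics are micro-averaged over pixels pooled across all evaluated images —
the dominant convention for DRIVE/STARE benchmarks — at threshold 0.5
(configurable).  All image pixels are scored, with no FOV restriction; an
FOV-restricted protocol would raise sensitivity-adjacent quantities and
lower specificity/accuracy, so numbers are not comparable across that
choice.  AUC is the Mann–Whitney statistic with average-rank ties, optionally
on a seeded pixel subsample for large pools.  Ratios that are 0/0 are
reported as 0.0 with an explicit flag rather than NaN; an AUC over
single-class truth raises instead, since any value would be arbitrary.

## Known limitations

* The engine is CPU-bound and float32; full-width 256×256 training at 500
  epochs is out of reach here and not attempted.
* `pretrained_backbone` is a loading hook; no weights ship with the package.
* The generator's background texture is stationary noise; real fundus
  backgrounds have structured texture that makes specificity harder.
* Stacking is fit on training-split predictions (see above).
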