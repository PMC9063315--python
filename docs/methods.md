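# Methods

## Problem

Segmenting the optic disc (OD) in wide-field fundus photographs of preterm
infants is the anchor step for zoning retinopathy of prematurity. These
RetCam-style images are difficult: non-uniform illumination, low contrast
between the disc and the orange fundus background, and frequently blurred
disc boundaries. The disc also occupies only a few percent of the frame, so
per-pixel objectives alone are dominated by background.

This package implements an attention-enhanced U-shaped encoder-decoder for
that task, together with a synthetic scene generator that reproduces the
qualitative difficulties above, so every part of the pipeline can be
exercised and tested without clinical data.

## Model

**Encoder.** A ResNet34 trunk with the classifier (global pooling + fully
connected layer) removed. Five taps are exposed: the stem convolution
output (64 channels at 1/2 resolution) and the four residual layers
(64 at 1/4, 128 at 1/8, 256 at 1/16, 512 at 1/32).

**DsSE (dual-scale semantic enhancement)** reconstructs the skip
connections at stages 2-4. For a current map F (C, H, W) and its
next-deeper neighbour N (2C, H/2, W/2):

1. N is mapped to C channels by a 1x1 convolution and bilinearly
   upsampled to (H, W);
2. 1x1 convolutions form the query Q from the upsampled N and the key K
   and value V from F, with Q and K at the compressed width C/r
   (r = 16; clamped below at 1 and logged);
3. after reshaping, the similarity E = softmax(Q K) is an (HW, HW) matrix
   whose rows are convex weights over all positions — softmax normalizes
   over the key axis so that the response is a weighted average of value
   vectors;
4. the spatial response T = V E^T is reshaped back to (C, H, W) and added
   residually: M = F + T.

With the row convention above each output pixel is a convex combination of
value vectors, checked in the tests against a brute-force per-pixel loop
oracle. Attention convolutions carry biases and no normalization layers.

**MsFF (multiscale feature fusion)** sits on top of the encoder. Stage-3
and stage-4 maps are max-pool downsampled (factors 4 and 2 — a
parameter-free choice that keeps the module's parameter cost at the
intended level) to the stage-5 grid. Each of the three maps passes through
its own AM gate — 1x1 conv to C/r, ReLU, 1x1 conv back to C, sigmoid —
giving a confidence map P_i in (0,1) and the gated feature Y_i = P_i * X_i.
The shallow outputs are projected to 512 channels by biased 1x1
convolutions and fused as

    Y_F = X5 + Y5 + (1 - P5) * (Y3' + Y4'),

so positions where the deepest gate is not confident (1 - P5 large) are
topped up with shallower detail. The AM gates run at each map's native
width; projecting to 512 channels only after gating is what keeps the
module's parameter increment at ~0.24 M (projecting first would roughly
double it).

**Decoder.** Four blocks, each: 1x1 convolution reducing width by a factor
of 4, a 3x3 stride-2 transposed convolution at the reduced width, and a
1x1 convolution to the target skip width; every convolution is followed by
batch normalization and ReLU. Channel plan 512-256-128-64-64. Skips fuse
by element-wise addition (the widths admit no concatenation under the
parameter budget; addition also matches the residual trunk's style). After
the last block the map is at 1/2 input resolution; the head (3x3 stride-2
deconvolution to 32 channels, 1x1 conv 32-32, 1x1 conv 32-1, the final
conv biased) restores full resolution and emits one logit per pixel.
Probabilities are thresholded at 0.5 with ties mapped to foreground —
stated once here, used everywhere.

**Parameter budget.** Trunk 21.28 M, decoder 0.33 M, head 0.02 M:
baseline 21.63 M. The three DsSE instances add 269,752 parameters
(+0.27 M) and MsFF adds 241,592 (+0.24 M); the full model is 22.14 M.
These land within 1% of the reference totals and 5% of the module deltas,
which is what pinned the open wiring choices: three DsSE instances on the
stage-2/3/4 skips (not the stem, not stage 5), additive skip fusion, and
AM-before-projection in MsFF.

## Loss and metrics

Training minimizes `L = L_Dice + L_BCE`: a soft Dice loss
`1 - 2(sum XY + eps)/(sum X + sum Y + eps)` with eps = 1 (configurable;
tests use the eps -> 0 limit analytically) and per-pixel-mean binary
cross-entropy with probabilities clipped to [1e-7, 1 - 1e-7]. BCE is
averaged rather than summed so loss magnitudes are independent of
resolution; `bce_reduction="sum"` restores the raw sum.

Evaluation: Dsc = 2TP/(2TP+FP+FN) and Sen = TP/(TP+FN) from pixel
confusion counts. Conventions for degenerate masks, chosen and logged:
both-empty gives Dsc = 1 (a vacuous perfect match); Sen is undefined on an
empty ground truth and such images are excluded from the Sen mean. Model
comparisons use a two-sided paired t-test on per-image Dsc; identical
score lists return p = 1.0 instead of NaN.

## Numerical core

No GPU framework is used: the package carries a small reverse-mode
autodiff engine over NumPy (`odseg.nn`). Convolutions are im2col views
contracted by BLAS; the transposed convolution and the convolution
input-gradient share one col2im scatter; bilinear resizing is a pair of
separable interpolation matrices (half-pixel centers), which makes its
adjoint exact. Batch normalization uses batch statistics in training
(running buffers updated with momentum 0.1, unbiased variance) and the
running buffers at evaluation. Every operation is verified against central
finite differences in float64. Weights are float32, He (fan-out) normal
initialized from a generator reset by `nn.manual_seed`, so construction is
reproducible; biases start at zero.

## Training protocol

Adam with initial learning rate 5e-4 and weight decay 1e-4 (classic L2
folded into the gradient), batch size 16, 100 epochs, constant learning
rate (no schedule is specified for the reference protocol; constant is the
simplest faithful reading), online augmentation of the training split
only, and checkpoint selection by best validation Dsc. Augmentation
applies, each with probability 0.5: horizontal flip, rotation uniform in
[-10, 10] degrees, and a small affine map (scale 0.9-1.1, translation up
to 5% per axis, shear up to 5 degrees), with identical geometry applied to
the image (bilinear) and mask (nearest-neighbor) so masks stay binary.

A zero learning rate is treated as a diagnostic "frozen" mode: no
parameter updates and no normalization-statistic drift, so validation
scores provably stay at initialization.

**Desk profile.** A named small-scale configuration used by the tests and
the acceptance script: quarter channel widths (stage ratio 1:1:2:4:8
preserved — the attention modules require exact width doubling between
adjacent stages), 128 x 128 inputs, 20 epochs, learning rate 5e-3. The
raised step size is deliberate: 20 epochs over a 64-image training set is
about 60 optimizer steps, two orders of magnitude fewer than the full
protocol, and Adam's per-step motion is proportional to the learning rate;
at 5e-4 the weights cannot leave the neighbourhood of their initialization
within the budget (measured plateau around val Dsc 0.43), while at 5e-3
the same run converges (best val Dsc 0.94, seed 7). All desk overrides are
logged at run time.

## Synthetic data

The generator emulates, at the native 640 x 480 resolution: a
reddish-orange fundus background under a smooth illumination field (linear
gradient plus radial falloff), a brighter elliptical disc (semi-axes 25-60
px, fully inside the canvas with a 5 px margin) whose boundary is Gaussian
blurred in the image only, 4-8 darker vessel-like Bezier curves radiating
from the disc center, additive Gaussian noise, and a bilinear resize to
256 x 256 (nearest-neighbor for the mask). The ground truth is the exact
ellipse interior: blur never touches the mask. Two difficulty classes:
"easy" (disc contrast 0.65-1.0, boundary blur sigma 1-3) and "blurred"
(contrast 0.15-0.35, sigma 3-6, the low-contrast regime that makes infant
fundus images hard). Disc size plus canvas fix the foreground fraction to
0.3-6% of pixels — the small-target regime the joint loss addresses.

Dataset splits use a floor-then-distribute rule (floor each fraction's
share, hand remainders out in train/val/test order); per-sample seeds
derive deterministically from the master seed, so datasets are
bit-reproducible. Everything about a scene is recorded in the manifest.

What this generator does **not** reproduce: real vascular branching
topology, pathology (hemorrhage, tunica vasculosa lentis, laser scars),
camera vignetting and chromatic response, or annotation noise. Passing
tests therefore demonstrate that the architecture, objective, and
optimization behave correctly and can learn disc segmentation in a
controlled regime — not that the reported clinical accuracy transfers to
patient data.

## Scale of the shipped experiments

Test-suite and acceptance runs are sized for a single CPU: oracle checks
use 4-16-channel maps on 2x2 to 8x8 grids; the end-to-end smoke run uses
the desk profile on 64 easy samples; the ablation harness's contract is
exercised on a 16-sample dataset at width 0.1. The full-protocol
configuration (256 x 256, full width, 100 epochs) is exposed through the
CLI and `TrainConfig` defaults for users with the compute and data to run
it.

## Known limitations

* No pretrained encoder weights ship with the package;
  `pretrained_encoder=True` raises unless users load their own checkpoint.
  Results at full scale will differ from a pretrained-encoder protocol.
* The CPU engine is single-threaded BLAS-bound; full-protocol training is
  impractical on it (it exists for correctness and small-scale study, and
  everything is checkpoint-compatible across scales).
* Synthetic-to-real transfer is out of scope by design (see above).
* The paired t-test inherits the usual normality-of-differences
  assumption; with per-image Dice differences on small test sets it should
  be read as approximate.
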