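# Methods

This note documents the modelling, numerical and design choices behind
the package, in the order a reader meets them: data, architecture, loss,
optimisation, uncertainty, and the scales at which everything is
exercised.

## Synthetic phantoms: what they emulate and what they do not

A phantom slice is a bright ellipse (the "gland", intensity 0.8 in
arbitrary units) on a darker background (0.2), with

* Gaussian edge blur (σ = 1.5 px) — creates the ambiguous-boundary regime
  that motivates the boundary loss term;
* a smooth multiplicative bias field (amplitude 0.2) — a low-order 2-D
  polynomial surface rescaled to exactly [1−m, 1+m], the simplest model
  of MRI intensity inhomogeneity;
* additive Gaussian noise (σ = 0.05), with Rician noise and motion blur
  available as explicit artifacts;
* optionally, dimmer distractor discs (off by default so the noise-free
  phantom is exactly two-valued, which several exact tests rely on).

The reference mask is the rasterised ellipse *before* any degradation, so
mask/image geometry is exact by construction. Ellipse semi-axes are drawn
uniformly from (40, 80) px at the 256 side (scaled proportionally by the
`small()` preset), centre within the middle fifth of the image, rotation
uniform — foreground fractions around 10–30 %, a realistic imbalance for
mid-gland prostate slices.

What the phantoms do **not** capture: heterogeneous internal gland
texture, zonal (peripheral/transition) anatomy, neighbouring organs with
similar intensity, inter-scanner protocol variation, and 3-D continuity
across slices. Tests passing on phantoms therefore demonstrate that the
architecture, loss and training loop are implemented correctly and can
learn a separable boundary-blurred target; they say nothing quantitative
about clinical performance.

## Encoder

Stock ResNet-50 bottleneck stages with three dense-prediction edits: no
max-pool after the stem (the stem convolution keeps its standard stride
2), stage-4 entry stride 1 instead of 2, and a dilated 3×3 in stage-4's
second bottleneck only. The resulting stage strides are {2, 4, 8, 8}.
The dilation rate defaults to 2 — the receptive-field analogue of the one
stride-2 that was removed; it is a configuration knob, not a claim.
Dropout (keep probability p, default 0.5 — note the *keep* convention;
any drop-rate interface must convert explicitly) follows each stage and
uses inverted scaling (kept units divided by p), so evaluation mode needs
no rescaling.

Presets: full widths (256/512/1024/2048, blocks 3/4/6/3) for 256×256
work; a "thin" preset (widths ÷8, blocks 1/1/1/2) for CPU-scale training
and CI. Stage 4 always has ≥2 blocks because the dilated convolution
lives in block 2.

## MSAF placement and widths

One MSAF block refines each of the stage-1..3 skips and, by default, the
deepest feature before the decoder (configurable, since reasonable
readings of the design differ). Branch width defaults to
input_channels/4; the transition activation defaults to PReLU to match
the branches, with a ReLU mode available because both appear in
descriptions of this block. 3×3 branches use zero padding equal to their
dilation so all five branch outputs stay spatially aligned for
concatenation. No gating/softmax attention coefficients are introduced:
the block is multi-branch fusion, and inventing a gate would change the
architecture.

## Decoder layout

The five decoder stages against a four-stage stride-{2,4,8,8} encoder are
arranged as: D5 on the deepest feature at stride 8; D4 at stride 8
(concatenating the stage-3 skip; no resolution change, mirroring the
stride-1 encoder stage); D3/D2/D1 upsample ×2 each via transposed
convolutions to strides 4, 2, 1. This is the only layout consistent with
both five fusion maps and the encoder's stride edits. Each stage ends in
a 1×1 single-channel head because the fusion sums maps across stages with
different native widths; the fusion itself uses fixed bilinear
upsampling (half-pixel convention, rows of the interpolation matrix sum
to 1, so constants are preserved exactly). The final threshold defaults
to 0.5. F2..F5 reach the training loss only through the fused sum.

## Loss

* **Dice**: ε = 1 by default (smoothing and empty-mask guard). λ defaults
  are (1, 1, 1); none of these values is prescribed by anything — they
  are surfaced prominently in `LossWeights` for exactly that reason.
* **Weighted cross-entropy**: the default mode multiplies only the
  foreground log-term by w = background/foreground (the reading under
  which an inverse-frequency weight counteracts imbalance); a
  global-scale mode (w outside the bracket) is provided as the literal
  alternative. Predictions are clamped to [1e-7, 1−1e-7] before logs,
  with gradients gated outside the clamp.
* **Boundary**: the exact form is the symmetric sum of Euclidean
  distances from each ground-truth contour point to the nearest predicted
  contour point and vice versa (contours: foreground pixels with a
  4-neighbour background pixel, image border counting as background).
  That is a function of binary point sets and not differentiable, so the
  trainable term evaluates the *soft* prediction on the
  thresholded-prediction contour weighted by the distance transform of
  the ground-truth contour, plus the reverse direction on the thresholded
  prediction held constant. On binary inputs the surrogate equals the
  exact computation (tested to 1e-6 on 50 random masks). Normalisation by
  total contour point count is on by default and switchable. If one
  contour is empty (a degenerate prediction early in training) the term
  returns a configured penalty constant (default 100) with a warning.

Losses are computed per slice and averaged over the batch; the
ground-truth contour distance transforms are precomputed once per
dataset.

## Optimisation and training loop

Adam (β = 0.9/0.999) at learning rate 1e-3 (choices 1e-2/1e-3/1e-4 are
the studied grid; batch sizes 4/8/16 likewise, default 8).
ReduceLROnPlateau on validation loss with factor 0.1 and patience 10, and
early stopping on validation loss with patience 20 — the mechanisms are
standard; these particular values are package defaults, exposed in
config. The best-validation-loss parameters are what a fit returns
(checkpoint selection by loss, not DSC, to match the early-stopping
criterion). Every stochastic element — initialisation, shuffling,
dropout — is driven by explicit seeded generators, and two runs with the
same seed produce bit-identical loss traces.

## Monte-Carlo dropout

Uncertainty prediction keeps only the dropout layers stochastic at
inference; batch norm stays on running statistics. T passes yield a mean
probability and per-pixel population variance. Where all T samples are
bit-identical the variance is set to exactly 0 (numpy's two-pass variance
otherwise leaves ~1e-32 rounding residue, which would break the exact
zero-variance contract for T = 1 or keep-prob 1).

## Numerical substrate

The network runs on a small reverse-mode autodiff engine over numpy
(`ranet.autodiff`): convolution via channels-last im2col gathers and BLAS
matmuls with a cached sparse col2im scatter in the backward pass;
transposed convolution as zero-insertion + flipped-kernel convolution;
fused batch norm; separable bilinear resizing as two small matrix
products. Every operation is gradient-checked against central finite
differences in float64 (tolerance 1e-5); models train in float32.

## Problem sizes used by the test-suite and acceptance script

Training demonstrations use the thin preset on eight 64×64 phantoms with
batch size 4 and at most 300 Adam steps — enough for the network to
essentially memorise separable synthetic glands (train DSC ≥ 0.95,
typically ≈ 0.96–0.99) in a few minutes on one CPU, which is the point of
the overfit sanity check: it validates gradients, loss wiring and the
optimisation loop end-to-end, not generalisation. Structure and shape
checks run the thin preset up to 256×256. The full-width preset is
provided for paper-scale experiments but is not exercised by the default
suite.

## Known limitations

* 2-D only; per-slice evaluation (per-volume aggregation exists as an
  option when reading real volumes, since slice-vs-volume averaging is
  genuinely ambiguous in this setting).
* No pretrained weights: the encoder trains from scratch.
* The accuracy metric follows the textual definition (TP+TN)/N; printed
  formulations that duplicate IoU for accuracy are treated as erroneous,
  since accuracy and IoU are reported as distinct quantities wherever
  both appear.
* "Hue/saturation" augmentation is undefined for single-channel data;
  the package offers an intensity-gamma analogue and a strict no-op mode
  rather than guessing an intent.
* DICOM ingestion, N4 bias correction, registration and multi-class
  zonal segmentation are out of scope.
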