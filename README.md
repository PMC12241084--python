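# ranet-seg

Segmentation of the prostate gland in 2-D T2-weighted MRI slices with a
residual attention encoder-decoder network, built and tested entirely on
synthetic prostate-like phantoms so that no clinical data download (and no
GPU) is needed to run, inspect or extend it.

The package targets researchers who want a transparent, fully seeded
reference implementation of this family of architectures: every layer,
the optimiser and the backward pass are plain numpy/scipy, gradient-checked
against finite differences, and wrapped in a scikit-learn-style estimator.

## The model

**Encoder — DilatedContextNet.** A ResNet-50-style bottleneck backbone
modified for dense prediction: the max-pool after the stem convolution is
removed, stage 4's stride-2 bottleneck is replaced by stride 1, and the 3×3
convolution in stage 4's *second* bottleneck is dilated (rate *r*, default
2), giving stage strides {2, 4, 8, 8} (output stride 8 — for a 256×256
input the stages are 128, 64, 32, 32 pixels on a side). A dropout layer
with keep probability *p* (default 0.5) follows each stage; leaving it
active at inference turns the network into an approximate Bayesian model
for Monte-Carlo uncertainty maps.

**Attention — MSAF.** Each skip connection passes through a Multi-Scale
Attention Fusion block: five parallel branches (1×1 conv; 3×3 convs at
dilations 1, 2, 3 — receptive extents 3, 5, 7; global image pooling), each
with PReLU, concatenated and restored to the input channel count by a 1×1
transition, so the block is shape-neutral.

**Decoder + FFM.** Five decoder stages D5..D1 mirror the encoder
(transposed-convolution upsampling, skip concatenation, two conv+PReLU
layers) and each ends in a single-channel head F_i. The Feature Fusion
Module bilinearly upsamples F2..F5 to input resolution and sums them:

    F_o  = Σ_{i=2..5} U(F_i),        Mask = σ(F_1 + F_o)

**Hybrid loss.**

    L = λ1·L_Dice + λ2·L_WCE + λ3·L_boundary

with L_Dice = 1 − (2Σyŷ + ε)/(Σy + Σŷ + ε); L_WCE a weighted binary
cross-entropy whose foreground weight w is the background/foreground pixel
ratio; and L_boundary the symmetric Euclidean distance between the
contours ∂y and ∂ŷ, trained through an equivalent distance-transform
surrogate (exact on binary masks, verified to 1e-6 in the tests).

Training follows Adam with a plateau learning-rate scheduler, at most 200
epochs and early stopping on validation loss; data splits are 70/20/10
train/val/test and real slices are resized to 256×256 and z-scored.

## Worked example

```python
import numpy as np
from ranet import PhantomParams, generate_dataset, RaNetSegmenter

splits = generate_dataset(n=20, params=PhantomParams.small(64), seed=0)
stack = lambda pairs: (np.stack([p.image.pixels for p in pairs]),
                       np.stack([p.mask.labels for p in pairs]))
X_train, y_train = stack(splits["train"])
X_test, y_test = stack(splits["test"])

seg = RaNetSegmenter(batch_size=4, max_epochs=60, max_steps=200,
                     early_stopping_patience=30, random_state=0,
                     validation_fraction=0.0)
seg.fit(X_train, y_train)
print(f"train DSC: {seg.score(X_train, y_train):.4f}")
print(f"test  DSC: {seg.score(X_test, y_test):.4f}")
report = seg.evaluate(X_test, y_test)
print({k: v['mean'] for k, v in report.to_json()['summary_pct'].items()})
mean, var = seg.predict_uncertainty(X_test[0], T=20, seed=0)
print(f"mean MC-dropout variance: {var.mean():.2e}")
```

prints (a few minutes on one CPU):

```
train DSC: 0.9555
test  DSC: 0.9419
{'dsc': 94.19, 'iou': 89.03, 'accuracy': 98.13, 'sensitivity': 92.63, 'specificity': 99.19}
mean MC-dropout variance: 3.33e-03
```

The train/test DSC are mean Dice overlaps between predicted and reference
gland masks on the 14 training and 2 held-out phantoms; the report row
gives the standard segmentation metrics as percentages; the Monte-Carlo
variance is the per-pixel spread over 20 stochastic dropout passes
(it concentrates along the gland boundary, where the segmentation is
genuinely ambiguous).

The same pipeline is scriptable from the shell (`ranet synth / train /
evaluate / predict / uncertainty / audit`, single YAML config); real
MetaImage (.mhd/.raw) and NIfTI volumes are read through
`ranet.imaging_io.read_volume`.

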