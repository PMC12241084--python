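"""DilatedContextNet: the modified ResNet-50-style encoder.

Three structural edits distinguish it from a stock ResNet-50 feature
extractor, all aimed at keeping spatial resolution for dense prediction:

* the max-pool that normally follows the stem convolution is removed, so
  the stem's stride-2 convolution is the only early downsampling;
* the first bottleneck of stage 4 uses stride 1 instead of stride 2, so
  the deepest stage stays at output stride 8;
* the 3x3 convolution of stage 4's *second* bottleneck is dilated
  (rate ``dilation_rate``) to recover the receptive field the removed
  stride would have provided.

A dropout layer follows each of the four stages. Keeping dropout active
at inference turns the encoder into an approximate Bayesian network for
Monte-Carlo uncertainty estimation; ``keep_prob`` is always the KEEP
probability (p in the 0.5-typical convention), never a drop rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor


@dataclass
class EncoderConfig:
    """Structural hyper-parameters of the encoder.

    ``stage_channels`` follows the ResNet-50 bottleneck convention
    (expanded widths); the ``thin`` preset divides widths by 8 and
    shortens the stages for CPU-scale experiments.
    """

    input_channels: int = 1
    stem_channels: int = 64
    stage_channels: tuple[int, int, int, int] = (256, 512, 1024, 2048)
    blocks_per_stage: tuple[int, int, int, int] = (3, 4, 6, 3)
    dilation_rate: int = 2
    keep_prob: float = 0.5

    def __post_init__(self):
        if self.dilation_rate < 1:
            raise ValueError(f"dilation_rate must be >= 1, got {self.dilation_rate}")
        if not 0.0 < self.keep_prob <= 1.0:
            raise ValueError(f"keep_prob must lie in (0, 1], got {self.keep_prob}")
        if any(c <= 0 for c in self.stage_channels) or self.stem_channels <= 0:
            raise ValueError("channel counts must be positive")
        if self.blocks_per_stage[3] < 2:
            raise ValueError("stage 4 needs at least two blocks "
                             "(the dilated convolution lives in block 2)")

    @classmethod
    def thin(cls, **overrides) -> "EncoderConfig":
        """Narrow preset (widths /8, short stages) for CPU-scale runs."""
        kw = dict(stem_channels=8, stage_channels=(32, 64, 128, 256),
                  blocks_per_stage=(1, 1, 1, 2))
        kw.update(overrides)
        return cls(**kw)


@dataclass
class FeaturePyramid:
    """Ordered post-dropout encoder outputs X'1..X'4 with their scale
    factors (input side / feature side)."""

    stages: list
    scale_factors: tuple = (2, 4, 8, 8)

    def __post_init__(self):
        if len(self.stages) != 4:
            raise ValueError("expected four encoder stages")


class Bottleneck(nn.Module):
    """1x1 reduce / 3x3 / 1x1 expand residual unit; the 3x3 carries the
    stride and (optionally) the dilation."""

    def __init__(self, in_ch: int, out_ch: int, *, stride: int = 1,
                 dilation: int = 1, rng=None, dtype=np.float32):
        super().__init__()
        mid = max(out_ch // 4, 1)
        self.stride = stride
        self.dilation = dilation
        self.conv1 = nn.Conv2d(in_ch, mid, 1, bias=False, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(mid, dtype=dtype)
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=stride, padding=dilation,
                               dilation=dilation, bias=False, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(mid, dtype=dtype)
        self.conv3 = nn.Conv2d(mid, out_ch, 1, bias=False, rng=rng, dtype=dtype)
        self.bn3 = nn.BatchNorm2d(out_ch, dtype=dtype)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                       bias=False, rng=rng, dtype=dtype)
            self.down_bn = nn.BatchNorm2d(out_ch, dtype=dtype)
        else:
            self.down_conv = None
            self.down_bn = None
        self.relu = nn.ReLU()

    def forward(self, x):
        out = self.relu(self.bn1(self.conv1(x)))
        out = self.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return self.relu(out + shortcut)


class DilatedContextNet(nn.Module):
    def __init__(self, config: EncoderConfig, *, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        c = config
        # stem keeps its standard stride 2; only the max-pool is removed
        self.stem_conv = nn.Conv2d(c.input_channels, c.stem_channels, 7,
                                   stride=2, padding=3, bias=False,
                                   rng=rng, dtype=dtype)
        self.stem_bn = nn.BatchNorm2d(c.stem_channels, dtype=dtype)
        self.relu = nn.ReLU()

        stage_strides = (1, 2, 2, 1)  # stage-4 stride-2 replaced by stride 1
        in_ch = c.stem_channels
        stages = []
        for si, (out_ch, n_blocks, stride) in enumerate(
                zip(c.stage_channels, c.blocks_per_stage, stage_strides)):
            blocks = []
            for bi in range(n_blocks):
                dil = c.dilation_rate if (si == 3 and bi == 1) else 1
                blocks.append(Bottleneck(
                    in_ch if bi == 0 else out_ch, out_ch,
                    stride=stride if bi == 0 else 1,
                    dilation=dil, rng=rng, dtype=dtype))
            stages.append(nn.Sequential(*blocks))
            in_ch = out_ch
        self.stage1, self.stage2, self.stage3, self.stage4 = stages
        self.dropouts = [nn.Dropout2d(c.keep_prob, seed=i) for i in range(4)]

    def forward(self, x: Tensor) -> FeaturePyramid:
        _, _, h, w = x.shape
        if h % 8 or w % 8:
            raise ValueError(f"input spatial side must be divisible by 8, got {h}x{w}")
        x = self.relu(self.stem_bn(self.stem_conv(x)))
        feats = []
        for stage, drop in zip((self.stage1, self.stage2, self.stage3, self.stage4),
                               self.dropouts):
            x = stage(x)
            x = drop(x)
            feats.append(x)
        return FeaturePyramid(stages=feats)


def build_encoder(config: EncoderConfig, *, seed: int = 0,
                  dtype=np.float32) -> DilatedContextNet:
    return DilatedContextNet(config, rng=np.random.default_rng(seed), dtype=dtype)


def encoder_forward(encoder: DilatedContextNet, batch: np.ndarray, *,
                    training: bool = False, seed: int | None = None) -> FeaturePyramid:
    """Run a (N, 1, H, W) or (N, H, W) batch through the encoder."""
    arr = np.asarray(batch)
    if arr.ndim == 3:
        arr = arr[:, None]
    encoder.train(training)
    if seed is not None:
        for i, d in enumerate(encoder.dropouts):
            d.reseed(seed + i)
    return encoder(Tensor(arr))


def apply_dropout(feature_map: np.ndarray, keep_prob: float, *,
                  training: bool = True, seed: int = 0) -> np.ndarray:
    """Standalone inverted dropout on a raw array.

    Each unit survives with probability ``keep_prob`` and is divided by
    ``keep_prob``, so the expectation is preserved; evaluation mode is the
    identity.
    """
    if not 0.0 < keep_prob <= 1.0:
        raise ValueError(f"keep_prob must lie in (0, 1], got {keep_prob}")
    x = np.asarray(feature_map)
    if not training or keep_prob == 1.0:
        return x.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(x.shape) < keep_prob
    return np.where(mask, x / keep_prob, 0.0)


def effective_kernel_extent(kernel_size: int, dilation: int) -> int:
    """Spatial extent of a dilated kernel: k + (k-1)(r-1)."""
    if kernel_size < 1 or dilation < 1:
        raise ValueError("kernel_size and dilation must be >= 1")
    return kernel_size + (kernel_size - 1) * (dilation - 1)


def audit_structure(encoder: DilatedContextNet, input_side: int = 256) -> dict:
    """Structural audit of the built graph (not of the config): pooling
    layers, stage-4 strides/dilations, and the stage spatial sides for a
    square input."""
    n_pool = sum(1 for _, m in encoder.named_modules()
                 if type(m).__name__.lower().startswith("maxpool"))
    stage4 = encoder.stage4.layers
    dilated = [(bi, blk.dilation) for bi, blk in enumerate(stage4)
               if blk.dilation > 1]
    side = input_side // 2  # stem stride 2, no pooling after it
    sides = []
    for stage in (encoder.stage1, encoder.stage2, encoder.stage3, encoder.stage4):
        side //= stage.layers[0].stride
        sides.append(side)
    return {
        "n_maxpool_after_stem": n_pool,
        "stage4_first_block_stride": stage4[0].stride,
        "n_dilated_convs_stage4": len(dilated),
        "dilated_block_indices": [bi for bi, _ in dilated],
        "dilation_rate": dilated[0][1] if dilated else 1,
        "stage_spatial_sides": tuple(sides),
        "n_parameters": sum(p.data.size for p in encoder.parameters()),
    }
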