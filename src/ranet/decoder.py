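"""Decoder and Feature Fusion Module (FFM).

The decoder mirrors the encoder with five stages D5..D1. Because the
modified encoder runs at strides {2, 4, 8, 8}, the layout that is
consistent with both a five-map fusion head and those strides is:

* D5 — convolutions on the deepest (stride-8) feature;
* D4 — stride 8, concatenated with the refined stage-3 skip (no
  resolution change, mirroring the encoder's stride-1 stage 4);
* D3/D2/D1 — transposed-convolution x2 upsampling to strides 4, 2, 1,
  with the refined stage-2 / stage-1 skips joined where one exists.

Each stage ends in a single-channel projection head F_i; the FFM
bilinearly upsamples F2..F5 to the input resolution and sums them, and
the final probability map is sigmoid(F1 + F_o).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .encoder import FeaturePyramid


@dataclass
class DecoderOutputs:
    """Per-stage single-channel logit maps F1..F5 (F1 at full input
    resolution) and their scale factors."""

    maps: dict  # {1: Tensor, ..., 5: Tensor}
    scale_factors: dict  # {1: 1, 2: 2, 3: 4, 4: 8, 5: 8}

    def __post_init__(self):
        if sorted(self.maps) != [1, 2, 3, 4, 5]:
            raise ValueError("decoder must produce exactly five maps F1..F5")
        if self.scale_factors[1] != 1:
            raise ValueError("F1 must be at full input resolution")
        for i, m in self.maps.items():
            if m.shape[1] != 1:
                raise ValueError(f"F{i} must be single-channel, got {m.shape[1]}")


@dataclass
class SegmentationOutput:
    probability_map: np.ndarray  # in (0, 1), input resolution
    binary_mask: np.ndarray  # {0, 1}
    threshold: float


class _ConvBlock(nn.Module):
    """Two 3x3 conv + BN + PReLU layers."""

    def __init__(self, in_ch, out_ch, *, rng, dtype):
        super().__init__()
        self.body = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 3, padding=1, bias=False, rng=rng, dtype=dtype),
            nn.BatchNorm2d(out_ch, dtype=dtype),
            nn.PReLU(out_ch, dtype=dtype),
            nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng, dtype=dtype),
            nn.BatchNorm2d(out_ch, dtype=dtype),
            nn.PReLU(out_ch, dtype=dtype))

    def forward(self, x):
        return self.body(x)


class Decoder(nn.Module):
    """Five-stage decoder over a (refined) feature pyramid.

    ``skip_channels`` are the channel counts of the refined stage-1..3
    skips; ``deep_channels`` that of the deepest feature handed to D5.
    """

    def __init__(self, deep_channels: int, skip_channels: tuple[int, int, int],
                 decoder_channels: tuple[int, int, int, int, int] = (128, 64, 32, 16, 16),
                 *, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c1, c2, c3 = skip_channels
        d5, d4, d3, d2, d1 = decoder_channels
        self.block5 = _ConvBlock(deep_channels, d5, rng=rng, dtype=dtype)
        self.block4 = _ConvBlock(d5 + c3, d4, rng=rng, dtype=dtype)
        self.up3 = nn.ConvTranspose2d(d4, d4, 2, stride=2, rng=rng, dtype=dtype)
        self.block3 = _ConvBlock(d4 + c2, d3, rng=rng, dtype=dtype)
        self.up2 = nn.ConvTranspose2d(d3, d3, 2, stride=2, rng=rng, dtype=dtype)
        self.block2 = _ConvBlock(d3 + c1, d2, rng=rng, dtype=dtype)
        self.up1 = nn.ConvTranspose2d(d2, d2, 2, stride=2, rng=rng, dtype=dtype)
        self.block1 = _ConvBlock(d2, d1, rng=rng, dtype=dtype)
        self.heads = [nn.Conv2d(dc, 1, 1, rng=rng, dtype=dtype)
                      for dc in (d1, d2, d3, d4, d5)]

    def forward(self, pyramid: FeaturePyramid, refined_skips: list) -> DecoderOutputs:
        s1, s2, s3 = refined_skips
        deep = pyramid.stages[3]
        for name, skip, ref in (("stage1", pyramid.stages[0], s1),
                                ("stage2", pyramid.stages[1], s2),
                                ("stage3", pyramid.stages[2], s3)):
            if skip.shape[2:] != ref.shape[2:]:
                raise ValueError(f"skip/pyramid scale mismatch at {name}: "
                                 f"{ref.shape[2:]} vs {skip.shape[2:]}")
        d5 = self.block5(deep)                       # stride 8
        d4 = self.block4(ad.concat([d5, s3], axis=1))  # stride 8
        d3 = self.block3(ad.concat([self.up3(d4), s2], axis=1))  # stride 4
        d2 = self.block2(ad.concat([self.up2(d3), s1], axis=1))  # stride 2
        d1 = self.block1(self.up1(d2))               # stride 1
        maps = {i + 1: self.heads[i](d) for i, d in enumerate((d1, d2, d3, d4, d5))}
        return DecoderOutputs(maps=maps,
                              scale_factors={1: 1, 2: 2, 3: 4, 4: 8, 5: 8})


def ffm_fuse(outputs: DecoderOutputs) -> Tensor:
    """F_o = sum over i=2..5 of bilinear-upsample(F_i) at input resolution."""
    for i in (2, 3, 4, 5):
        if i not in outputs.maps:
            raise ValueError(f"missing decoder stage map F{i}")
    target = outputs.maps[1].shape[2:]
    fo = None
    for i in (2, 3, 4, 5):
        up = ad.bilinear_upsample(outputs.maps[i], target)
        fo = up if fo is None else fo + up
    return fo


def predict_mask(f1, fo, threshold: float = 0.5) -> SegmentationOutput:
    """Mask = sigmoid(F1 + F_o), thresholded."""
    t1 = f1 if isinstance(f1, Tensor) else Tensor(np.asarray(f1))
    to = fo if isinstance(fo, Tensor) else Tensor(np.asarray(fo))
    if t1.shape != to.shape:
        raise ValueError(f"F1 {t1.shape} and F_o {to.shape} must share a shape")
    prob = ad.sigmoid(t1 + to).data
    return SegmentationOutput(probability_map=prob,
                              binary_mask=(prob >= threshold).astype(np.uint8),
                              threshold=threshold)
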