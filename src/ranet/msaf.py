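"""Multi-Scale Attention Fusion (MSAF) block for skip connections.

Five parallel branches look at the same encoder feature map at different
receptive extents — 1x1, 3x3 with dilation 1/2/3 (extents 3, 5, 7), and a
global image-pooling branch — their outputs are concatenated and a 1x1
transition convolution restores the input channel count, so the block is
a shape-neutral drop-in refinement on any skip connection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass
class MSAFConfig:
    branch_width: int | None = None  # None -> input_channels // 4
    transition_activation: str = "prelu"  # {"prelu", "relu"}
    apply_to_deepest: bool = True

    def __post_init__(self):
        if self.transition_activation not in ("prelu", "relu"):
            raise ValueError(
                f"unknown transition activation {self.transition_activation!r}")


def global_image_pool(x) -> Tensor:
    """Per-channel spatial mean broadcast back to the input's spatial dims."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    pooled = ad.tmean(t, axis=(2, 3), keepdims=True)
    return ad.broadcast_to(pooled, t.shape)


def _act(kind: str, channels: int, dtype):
    return nn.PReLU(channels, dtype=dtype) if kind == "prelu" else nn.ReLU()


class MSAF(nn.Module):
    def __init__(self, in_channels: int, config: MSAFConfig | None = None, *,
                 rng=None, dtype=np.float32):
        super().__init__()
        config = config or MSAFConfig()
        rng = rng or np.random.default_rng(0)
        bw = config.branch_width or max(in_channels // 4, 1)
        self.in_channels = in_channels
        self.branch_width = bw
        act = config.transition_activation

        def conv_branch(k, dil):
            pad = dil * (k // 2)
            return nn.Sequential(
                nn.Conv2d(in_channels, bw, k, padding=pad, dilation=dil,
                          rng=rng, dtype=dtype),
                nn.PReLU(bw, dtype=dtype))

        self.branch_1x1 = conv_branch(1, 1)
        self.branch_3x3_d1 = conv_branch(3, 1)
        self.branch_3x3_d2 = conv_branch(3, 2)
        self.branch_3x3_d3 = conv_branch(3, 3)
        # image-pooling branch: global mean, then a 1x1 projection
        self.pool_proj = nn.Sequential(
            nn.Conv2d(in_channels, bw, 1, rng=rng, dtype=dtype),
            nn.PReLU(bw, dtype=dtype))
        self.transition = nn.Conv2d(5 * bw, in_channels, 1, rng=rng, dtype=dtype)
        self.transition_act = _act(act, in_channels, dtype)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        if h < 1 or w < 1:
            raise ValueError("MSAF needs positive spatial dims")
        branches = [
            self.branch_1x1(x),
            self.branch_3x3_d1(x),
            self.branch_3x3_d2(x),
            self.branch_3x3_d3(x),
            self.pool_proj(global_image_pool(x)),
        ]
        fused = ad.concat(branches, axis=1)
        return self.transition_act(self.transition(fused))


def msaf_forward(block: MSAF, feature_map: np.ndarray) -> np.ndarray:
    """Functional wrapper: refine a raw (N, C, H, W) array, eval mode."""
    block.eval()
    return block(Tensor(np.asarray(feature_map))).data
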