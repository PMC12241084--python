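"""Full network: dilated-context encoder + MSAF-refined skips + decoder
with feature-fusion head.

``RaNet.forward`` returns the per-stage logit maps, the fused map and the
sigmoid probability map for a batch; checkpoints carry an architecture
fingerprint so an incompatible load fails loudly.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .decoder import Decoder, DecoderOutputs, ffm_fuse
from .encoder import DilatedContextNet, EncoderConfig, FeaturePyramid
from .msaf import MSAF, MSAFConfig


class RaNet(nn.Module):
    """Encoder-decoder segmentation network with attention-fused skips.

    One MSAF block refines each of the stage-1..3 skip connections and
    (by default) the deepest encoder feature before it enters the
    decoder.
    """

    def __init__(self, encoder_config: EncoderConfig | None = None,
                 msaf_config: MSAFConfig | None = None,
                 decoder_channels: tuple[int, int, int, int, int] | None = None,
                 *, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.encoder_config = encoder_config or EncoderConfig()
        self.msaf_config = msaf_config or MSAFConfig()
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = self.encoder_config.stage_channels
        if decoder_channels is None:
            decoder_channels = (max(c4 // 2, 8), max(c4 // 4, 8),
                                max(c4 // 8, 8), max(c4 // 16, 8),
                                max(c4 // 16, 8))
        self.decoder_channels = tuple(decoder_channels)
        self.encoder = DilatedContextNet(self.encoder_config, rng=rng, dtype=dtype)
        self.msaf1 = MSAF(c1, self.msaf_config, rng=rng, dtype=dtype)
        self.msaf2 = MSAF(c2, self.msaf_config, rng=rng, dtype=dtype)
        self.msaf3 = MSAF(c3, self.msaf_config, rng=rng, dtype=dtype)
        self.msaf_deep = (MSAF(c4, self.msaf_config, rng=rng, dtype=dtype)
                          if self.msaf_config.apply_to_deepest else None)
        self.decoder = Decoder(c4, (c1, c2, c3), self.decoder_channels,
                               rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> dict:
        pyramid = self.encoder(x)
        skips = [self.msaf1(pyramid.stages[0]),
                 self.msaf2(pyramid.stages[1]),
                 self.msaf3(pyramid.stages[2])]
        deep = pyramid.stages[3]
        if self.msaf_deep is not None:
            deep = self.msaf_deep(deep)
            pyramid = FeaturePyramid(stages=pyramid.stages[:3] + [deep],
                                     scale_factors=pyramid.scale_factors)
        outputs: DecoderOutputs = self.decoder(pyramid, skips)
        fo = ffm_fuse(outputs)
        logits = outputs.maps[1] + fo
        prob = ad.sigmoid(logits)
        return {"prob": prob, "logits": logits, "fused": fo,
                "decoder_outputs": outputs, "pyramid": pyramid}

    # -- uncertainty mode ---------------------------------------------
    def dropout_modules(self) -> list[nn.Dropout2d]:
        return [m for _, m in self.named_modules()
                if isinstance(m, nn.Dropout2d)]

    def set_mc_dropout(self, active: bool, seed: int | None = None):
        """Toggle stochastic dropout during evaluation (batch norm stays
        on running statistics)."""
        for i, d in enumerate(self.dropout_modules()):
            d.mc_active = active
            if seed is not None:
                d.reseed(seed + i)

    # -- checkpointing -------------------------------------------------
    def fingerprint(self) -> str:
        return json.dumps({
            "encoder": asdict(self.encoder_config),
            "msaf": asdict(self.msaf_config),
            "decoder_channels": list(self.decoder_channels),
        }, sort_keys=True)

    def save_checkpoint(self, path):
        state = self.state_dict()
        np.savez(path, __fingerprint__=np.array(self.fingerprint()), **state)

    def load_checkpoint(self, path):
        with np.load(path, allow_pickle=False) as data:
            fp = str(data["__fingerprint__"])
            if fp != self.fingerprint():
                raise ValueError(
                    "checkpoint/architecture mismatch:\n"
                    f"  checkpoint: {fp}\n  model:      {self.fingerprint()}")
            self.load_state_dict({k: data[k] for k in data.files
                                  if k != "__fingerprint__"})
        return self


def thin_ranet(*, seed: int = 0, dilation_rate: int = 2,
               keep_prob: float = 0.5, msaf_config: MSAFConfig | None = None,
               dtype=np.float32) -> RaNet:
    """CPU-scale preset: /8 widths, short stages."""
    cfg = EncoderConfig.thin(dilation_rate=dilation_rate, keep_prob=keep_prob)
    return RaNet(cfg, msaf_config, seed=seed, dtype=dtype)


def paper_scale_ranet(*, seed: int = 0, dilation_rate: int = 2,
                      keep_prob: float = 0.5,
                      msaf_config: MSAFConfig | None = None,
                      dtype=np.float32) -> RaNet:
    """Full-width ResNet-50-style preset for 256x256 inputs."""
    cfg = EncoderConfig(dilation_rate=dilation_rate, keep_prob=keep_prob)
    return RaNet(cfg, msaf_config, seed=seed, dtype=dtype)
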