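"""Single-YAML configuration mirroring the module surfaces.

Sections: ``data`` (phantom generation + augmentation), ``encoder``,
``msaf``, ``decoder``, ``loss``, ``train``. Every field name matches the
corresponding dataclass field, so a config round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .encoder import EncoderConfig
from .imaging_io import AugmentationPlan
from .losses import LossWeights
from .msaf import MSAFConfig
from .phantom import PhantomParams
from .training import TrainConfig


@dataclass
class DataConfig:
    n: int = 20
    split_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0
    target_side: int | None = None  # resize+z-score when set
    phantom: PhantomParams = field(default_factory=PhantomParams)
    augmentation: AugmentationPlan = field(default_factory=AugmentationPlan)


@dataclass
class DecoderSection:
    channels: tuple[int, int, int, int, int] | None = None
    threshold: float = 0.5


@dataclass
class PipelineConfig:
    data: DataConfig = field(default_factory=DataConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig.thin)
    msaf: MSAFConfig = field(default_factory=MSAFConfig)
    decoder: DecoderSection = field(default_factory=DecoderSection)
    loss: LossWeights = field(default_factory=LossWeights)
    train: TrainConfig = field(default_factory=TrainConfig)


_SECTION_TYPES = {
    "encoder": EncoderConfig,
    "msaf": MSAFConfig,
    "decoder": DecoderSection,
    "loss": LossWeights,
    "train": TrainConfig,
}


def _tuplify(cls, kwargs: dict) -> dict:
    out = {}
    for k, v in kwargs.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    if "data" in raw:
        d = dict(raw["data"])
        phantom = PhantomParams(**_tuplify(PhantomParams, d.pop("phantom", {})))
        augmentation = AugmentationPlan(
            **_tuplify(AugmentationPlan, d.pop("augmentation", {})))
        cfg.data = DataConfig(phantom=phantom, augmentation=augmentation,
                              **_tuplify(DataConfig, d))
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            setattr(cfg, section, cls(**_tuplify(cls, raw[section])))
    return cfg


def save_config(cfg: PipelineConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
    return path
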