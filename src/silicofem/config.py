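"""Pipeline configuration: nested dataclasses with lossless YAML round trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import CohortConfig, DensityParams, TemplateConfig
from .risk import FallConstants
from .sampler import SamplingConfig
from .strength import StrengthConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end experiment needs, stage by stage."""

    n_pairs: int = 47
    n_synthetic: int = 1080
    cohort: CohortConfig = field(default_factory=CohortConfig)
    block_scale: float = 1.0
    equalize_blocks: bool = False
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    strength: StrengthConfig = field(default_factory=StrengthConfig)
    fall: FallConstants = field(default_factory=FallConstants)
    fall_rate: float = 0.65
    write_meshes: bool = False

    def validate(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        self.cohort.template.validate()
        self.cohort.density.validate()
        self.sampling.validate()
        if self.block_scale <= 0:
            raise ValueError("block_scale must be positive")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


_NESTED = {
    "cohort": CohortConfig,
    "template": TemplateConfig,
    "density": DensityParams,
    "sampling": SamplingConfig,
    "strength": StrengthConfig,
    "fall": FallConstants,
}


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in _NESTED and isinstance(v, dict):
            kwargs[f.name] = _build(_NESTED[f.name], v)
        elif isinstance(v, list):
            kwargs[f.name] = tuple(v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


def save_config(path, config: PipelineConfig) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return _build(PipelineConfig, data or {})
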