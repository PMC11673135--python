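"""Pipeline configuration with YAML round-tripping.

A :class:`PipelineConfig` gathers preprocessing toggles, the optimiser
configurations and search bounds, accumulation options and the global seed.
The global seed propagates into both optimiser configs unless they were given
explicit seeds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .optimizers import CPSOConfig, GAConfig, SearchBounds

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    grayscale_average: bool = True
    mean_filter: bool = True
    register_on_denoised: bool = True  # registration sees the denoised frames
    ga: GAConfig = field(default_factory=GAConfig)
    cpso: CPSOConfig = field(default_factory=CPSOConfig)
    bounds: SearchBounds = field(default_factory=SearchBounds)
    max_frames: int | None = None
    normalization: str = "mean"  # "mean" | "sum" for metric computation
    entropy_levels: int = 256
    downsample: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalization not in ("mean", "sum"):
            raise ValueError("normalization must be 'mean' or 'sum'")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")

    def seeded(self) -> "PipelineConfig":
        """Copy with the global seed pushed into both optimiser configs."""
        return replace(
            self,
            ga=replace(self.ga, rng_seed=self.seed),
            cpso=replace(self.cpso, rng_seed=self.seed + 1),
        )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["bounds"] = {
            "tx": list(self.bounds.tx),
            "ty": list(self.bounds.ty),
            "theta": list(self.bounds.theta),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        if "ga" in kwargs and isinstance(kwargs["ga"], dict):
            kwargs["ga"] = GAConfig(**kwargs["ga"])
        if "cpso" in kwargs and isinstance(kwargs["cpso"], dict):
            kwargs["cpso"] = CPSOConfig(**kwargs["cpso"])
        if "bounds" in kwargs and isinstance(kwargs["bounds"], dict):
            b = kwargs["bounds"]
            kwargs["bounds"] = SearchBounds(
                tx=tuple(b["tx"]), ty=tuple(b["ty"]), theta=tuple(b["theta"])
            )
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)
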