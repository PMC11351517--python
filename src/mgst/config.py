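"""Pipeline configuration: every analysis threshold in one serializable
object, defaulting to the protocol's printed values."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .paradigm import ParadigmSpec, ScreenGeometry
from .trials import TrialRules

__all__ = ["PreprocessConfig", "IVTConfig", "StatsConfig", "PipelineConfig"]


@dataclass(frozen=True)
class PreprocessConfig:
    gap_fill_ms: float = 75.0
    velocity_window_ms: float = 20.0


@dataclass(frozen=True)
class IVTConfig:
    threshold_deg_s: float = 30.0
    merge_time_ms: float = 75.0
    merge_angle_deg: float = 0.5
    min_fixation_ms: float = 60.0


@dataclass(frozen=True)
class StatsConfig:
    method: str = "spearman"
    alpha: float = 0.05
    fdr: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ivt: IVTConfig = field(default_factory=IVTConfig)
    trials: TrialRules = field(default_factory=TrialRules)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["paradigm"] = self.paradigm.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            geometry=ScreenGeometry(**d.get("geometry", {})),
            paradigm=ParadigmSpec.from_dict(d.get("paradigm", {})),
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            ivt=IVTConfig(**d.get("ivt", {})),
            trials=TrialRules(**d.get("trials", {})),
            stats=StatsConfig(**d.get("stats", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
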