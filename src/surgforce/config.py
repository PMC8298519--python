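"""Pipeline configuration: one serializable object covering every stage.

Precedence is CLI flags > config file > defaults; the effective config and
its hash are logged before any stage runs so runs are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .features import FeatureConfig
from .preprocess import FilterSpec


@dataclass(frozen=True)
class PipelineConfig:
    filter: FilterSpec = FilterSpec()
    features: FeatureConfig = FeatureConfig()
    screening_mode: str = "fixed"
    screening_alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown config keys {sorted(unknown)}")
        if "filter" in data:
            data["filter"] = FilterSpec(**data["filter"])
        if "features" in data:
            data["features"] = FeatureConfig(**data["features"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        return cls.from_dict(loaded)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
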