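"""Validated pipeline configuration with YAML round-tripping.

``PipelineConfig`` nests one configuration object per pipeline stage; every
field is validated by its stage's dataclass on load, unknown keys are
rejected, and the fully defaulted configuration can be echoed back to YAML
for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .classifier import NetworkConfig
from .dataset_types import LabelConfig
from .features import FeatureConfig
from .postprocess import PostprocessConfig
from .preprocess import PreprocessConfig
from .segmentation import SlicConfig
from .synthetic import SyntheticSpec

__all__ = ["ConfigError", "EvaluationConfig", "PipelineConfig"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a configuration file."""


@dataclass
class EvaluationConfig:
    """Evaluation-stage parameters (image-level acceptability proxy)."""

    iou_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_threshold <= 1.0:
            raise ConfigError("iou_threshold must lie in (0, 1]")


_SECTIONS: dict[str, type] = {
    "preprocess": PreprocessConfig,
    "slic": SlicConfig,
    "features": FeatureConfig,
    "dataset": LabelConfig,
    "network": NetworkConfig,
    "postprocess": PostprocessConfig,
    "evaluation": EvaluationConfig,
    "synthetic": SyntheticSpec,
}


def _build_section(cls: type, data: dict[str, Any], section: str) -> Any:
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"section {section!r}: {exc}") from exc


@dataclass
class PipelineConfig:
    """Top-level configuration: one section per stage plus a global seed."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    slic: SlicConfig = field(default_factory=SlicConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    dataset: LabelConfig = field(default_factory=LabelConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    rng_seed: int = 0

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict[str, Any] = {}
        for section, section_cls in _SECTIONS.items():
            if section in data:
                raw = data.pop(section)
                if not isinstance(raw, dict):
                    raise ConfigError(f"section {section!r} must be a mapping")
                kwargs[section] = _build_section(section_cls, raw, section)
        if "rng_seed" in data:
            kwargs["rng_seed"] = int(data.pop("rng_seed"))
        if data:
            raise ConfigError(f"unknown top-level key(s) {sorted(data)}")
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for section in _SECTIONS:
            obj = getattr(self, section)
            sec = dataclasses.asdict(obj)
            out[section] = {
                k: list(v) if isinstance(v, tuple) else v for k, v in sec.items()
            }
        out["rng_seed"] = self.rng_seed
        return out

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration root must be a mapping")
        return cls.from_dict(raw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        """Stable digest of the effective configuration, for provenance."""
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
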