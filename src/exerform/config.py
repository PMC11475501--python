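"""Run configuration: YAML-backed, schema-validated with pydantic."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .classify import ModelConfig
from .features import WindowSpec

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration failed schema validation; message names the bad key."""


class WindowSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    size: int = 30
    step: int = 15
    fs: float = 30.0
    band: tuple[float, float] = (1.0, 20.0)


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    variance_target: float = Field(0.95, gt=0.0, le=1.0)
    min_components: int = Field(2, ge=1)
    cv_mode: str = "window"


class IMUSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    auto_mask: bool = False
    mask_window_s: float = 0.5
    mask_std_threshold: float = 0.02
    min_pairs: int = 5


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    trials_per_class: int = Field(20, ge=1)
    imu_subjects: int = Field(10, ge=1)


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    window: WindowSection = WindowSection()
    model: ModelSection = ModelSection()
    imu: IMUSection = IMUSection()
    simulate: SimulateSection = SimulateSection()
    seed: int = 0
    log_level: str = "INFO"

    def window_spec(self) -> WindowSpec:
        w = self.window
        return WindowSpec(size=w.size, step=w.step, fs=w.fs, band=tuple(w.band))

    def model_config_obj(self) -> ModelConfig:
        m = self.model
        return ModelConfig(
            kernel=m.kernel, C=m.C, gamma=m.gamma, variance_target=m.variance_target,
            min_components=m.min_components, cv_mode=m.cv_mode, seed=self.seed,
        )

    def digest(self) -> str:
        """Stable hash of the validated configuration, for provenance headers."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; missing path means defaults."""
    if path is None:
        return RunConfig()
    try:
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.model_validate(doc)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config key {loc!r}: {first['msg']}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
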