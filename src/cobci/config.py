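"""Run configuration: a validated, schema-checked view of a YAML/JSON file.

Every section mirrors a pipeline stage. Unknown keys are rejected so typos
fail loudly before any computation starts.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "load_config", "ConfigFileError"]


class ConfigFileError(ValueError):
    """Configuration file missing, unparseable, or schema-invalid."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_subjects: int = Field(default=20, ge=1)
    trials_per_condition: int = Field(default=100, ge=1)
    sampling_rate_hz: float = Field(default=256.0, gt=0)
    epoch_window_ms: tuple[float, float] = (-100.0, 700.0)
    noise_kind: str = Field(default="ar1", pattern="^(white|ar1|pink)$")
    calibrate: bool = True
    target_accuracy_range: tuple[float, float] = (0.56, 0.76)


class FeatureSection(_Strict):
    window_ms: tuple[float, float] = (0.0, 400.0)
    factor: int = Field(default=5, ge=1)
    normalize_mode: str = Field(default="fold", pattern="^(fold|pooled)$")
    baseline_ms: tuple[float, float] = (-100.0, 0.0)


class FusionSection(_Strict):
    method: str = Field(default="voting", pattern="^(single|averaging|concatenating|voting)$")
    sigma: float = Field(default=10.0, gt=0)
    C: float = Field(default=1.0, gt=0)


class EvalSection(_Strict):
    repeats: int = Field(default=10, ge=1)
    folds: int = Field(default=10, ge=2)
    stratified: bool = True
    resamples: int = Field(default=500, ge=1)
    n_range: list[int] | None = None
    window_offsets_ms: list[float] | None = None
    subject_counts: list[int] = [1, 5, 10, 15, 20]


class RunConfig(_Strict):
    simulation: SimSection = SimSection()
    features: FeatureSection = FeatureSection()
    fusion: FusionSection = FusionSection()
    evaluation: EvalSection = EvalSection()
    output_dir: str = "out"
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigFileError(f"config file not found: {path}")
    text = path.read_text()
    try:
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigFileError(f"cannot parse {path}: {exc}") from exc
    if payload is None:
        payload = {}
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigFileError(
            f"invalid config {path}: field '{loc}': {first['msg']}"
        ) from exc
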