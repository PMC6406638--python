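"""Validated run configuration (YAML-backed, strict schema)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticConfig(_Strict):
    n_novice: int = Field(5, ge=0)
    n_expert: int = Field(3, ge=0)
    fs: float = Field(128.0, ge=64.0)
    duration_scale: float = Field(1.0, gt=0)
    noise_sd: float = Field(1.0, gt=0)
    line_noise_amplitude: float = Field(0.5, ge=0)


class PreprocessConfig(_Strict):
    filter_order: int = Field(300, ge=2)
    lowpass_hz: float = 45.0
    highpass_hz: float = 0.1
    notch_hz: list[float] = Field(default_factory=lambda: [50.0, 60.0])
    amplitude_limit: float = Field(100.0, gt=0)
    epoch_seconds: float = Field(2.0, gt=0)
    epoch_step_seconds: float = Field(2.5, gt=0)


class ConnectivityConfig(_Strict):
    B: int = Field(4, ge=2)
    n_shuffles: int = Field(20, ge=1)


class GraphsConfig(_Strict):
    threshold: float = Field(0.001, ge=0)
    n_random: int = Field(100, ge=1)


class ClassifyConfig(_Strict):
    classifier: str = "knn"
    k: int = Field(3, ge=1)
    cv_folds: int = Field(5, ge=2)
    max_features: int | None = None
    window_seconds: float = Field(20.0, gt=0)
    window_step_seconds: float = Field(1.0, gt=0)


class RunConfig(_Strict):
    """One block per pipeline stage plus the master seed and state list."""

    seed: int = 0
    states: list[str] = Field(
        default_factory=lambda: ["rest", "drawing", "manipulation"])
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    connectivity: ConnectivityConfig = Field(
        default_factory=ConnectivityConfig)
    graphs: GraphsConfig = Field(default_factory=GraphsConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(),
                                             sort_keys=True))


def validate_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; an empty/missing file gives the
    defaults. Unknown keys or wrong types raise with the offending key."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config {path} must be a YAML mapping")
            data = loaded
    if overrides:
        data = _deep_merge(data, overrides)
    return RunConfig(**data)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
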