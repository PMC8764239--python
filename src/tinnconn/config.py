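"""Validated pipeline configuration with YAML round-trip.

Unknown keys are rejected (``extra='forbid'``); every section has defaults
so a minimal config file (or none at all) is runnable.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .types import ConfigurationError

__all__ = [
    "SimulationSection",
    "PreprocessSection",
    "FeatureSection",
    "ClassifierSection",
    "AnalysisSection",
    "PipelineConfig",
    "load_config",
    "save_config",
]

FEATURE_NAMES = ("plv", "pli", "pcc", "te", "rhythm", "psd")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSection(_Strict):
    scenario: str = "default"
    sampling_rate: float = 500.0
    duration: float = 130.0
    recordings_per_class: Union[int, List[int]] = 1
    n_epochs_target: Optional[int] = None


class PreprocessSection(_Strict):
    low_hz: float = 0.5
    high_hz: float = 90.0
    line_hz: Optional[float] = 50.0
    reference: str = "average"
    channels: Optional[List[str]] = None
    epoch_s: float = 10.0
    reject_threshold_uv: Optional[float] = None


class FeatureSection(_Strict):
    measures: List[str] = ["pcc", "plv"]
    band: Optional[str] = None  # band name; None = broadband
    te_bins: int = 4
    te_lag: int = 1

    def model_post_init(self, _ctx) -> None:
        bad = [m for m in self.measures if m not in FEATURE_NAMES]
        if bad:
            raise ValueError(f"unknown feature measures {bad}; choose from {FEATURE_NAMES}")


class ClassifierSection(_Strict):
    kinds: List[str] = ["svm_10cv", "mlp"]
    n_repeats: int = 10
    mlp_max_iter: int = 380
    mlp_hidden: List[int] = [200, 200]
    mlp_alpha: float = 1e-7
    mlp_learning_rate_init: float = 0.001


class AnalysisSection(_Strict):
    alpha: float = 0.05
    correction: Optional[str] = None
    threshold_fraction: float = 0.3
    mds_dims: int = 2
    control_label: str = "healthy"


class PipelineConfig(_Strict):
    seed: int = 0
    output_dir: str = "runs/tinnconn"
    input_recordings: Optional[List[str]] = None  # load these instead of simulating
    simulation: SimulationSection = SimulationSection()
    preprocess: PreprocessSection = PreprocessSection()
    features: FeatureSection = FeatureSection()
    classifiers: ClassifierSection = ClassifierSection()
    analysis: AnalysisSection = AnalysisSection()

    def to_dict(self) -> dict:
        return self.model_dump()


def load_config(path=None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Load and validate a YAML config; ``overrides`` is a shallow dict of
    section → {key: value} applied on top."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"no such config file: {path}")
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigurationError(f"{path}: config must be a mapping")
            data = loaded
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(data.get(key), dict):
            data[key] = {**data[key], **val}
        else:
            data[key] = val
    try:
        return PipelineConfig(**data)
    except (ValidationError, ValueError) as exc:
        raise ConfigurationError(f"invalid configuration: {exc}") from exc


def save_config(config: PipelineConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path
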