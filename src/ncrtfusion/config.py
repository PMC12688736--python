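"""Run configuration: one YAML file drives every pipeline stage.

Every field has a default; unknown keys are rejected so typos fail loudly.
The resolved configuration is echoed into every output file's metadata block.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .ablation import AblationConfig
from .cohort import GeneratorConfig, default_config
from .evaluation import METRIC_KEYS, ModelConfig
from .fusion import FusionConfig


class ConfigError(ValueError):
    """A configuration file key or value is invalid."""


@dataclass
class ScreeningSettings:
    alpha: float = 0.05


@dataclass
class EvaluationSettings:
    endpoint: str = "good_vs_poor"
    n_repeats: int = 5
    base_seed: int = 0


@dataclass
class AblationSettings:
    n_repeats: int = 5
    base_seed: int = 0
    top_k: int = 50
    proportion_mode: str = "slot_share"
    metrics: tuple[str, ...] = METRIC_KEYS
    cache_dir: str | None = None


@dataclass
class SVMSettings:
    C: float = 1.0
    gamma: str | float = "scale"


@dataclass
class RunConfig:
    """All tunables of the pipeline, one section per stage."""

    generator: GeneratorConfig = field(default_factory=default_config)
    screening: ScreeningSettings = field(default_factory=ScreeningSettings)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    svm: SVMSettings = field(default_factory=SVMSettings)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)
    ablation: AblationSettings = field(default_factory=AblationSettings)
    output_dir: str = "."

    def model_config(self) -> ModelConfig:
        cfg = ModelConfig(
            fusion=self.fusion,
            svm_C=self.svm.C,
            svm_gamma=self.svm.gamma,
            endpoint=self.evaluation.endpoint,
        )
        cfg.validate()
        return cfg

    def ablation_config(self) -> AblationConfig:
        return AblationConfig(
            model=self.model_config(),
            n_repeats=self.ablation.n_repeats,
            base_seed=self.ablation.base_seed,
            cache_dir=self.ablation.cache_dir,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _update_dataclass(obj, data: dict, path: str):
    valid = {f.name: f for f in fields(obj)}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown config key {path}{key!r}")
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value, f"{path}{key}.")
        elif isinstance(current, dict) and isinstance(value, dict):
            merged = dict(current)
            merged.update(value)
            setattr(obj, key, merged)
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            setattr(obj, key, tuple(value))
        else:
            setattr(obj, key, value)
    return obj


def load_config(path: str | Path | None = None) -> RunConfig:
    """RunConfig from a YAML file (or pure defaults when path is None)."""
    cfg = RunConfig()
    if path is None:
        return cfg
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as err:
        raise ConfigError(f"malformed YAML in {path}: {err}") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _update_dataclass(cfg, raw, "")
    try:
        cfg.generator.validate()
        cfg.fusion.validate()
        cfg.model_config()
        if not 0.0 < cfg.screening.alpha <= 1.0:
            raise ValueError("screening.alpha must be in (0, 1]")
        if cfg.ablation.top_k < 1:
            raise ValueError("ablation.top_k must be >= 1")
    except ValueError as err:
        raise ConfigError(str(err)) from None
    return cfg
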