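"""Configuration dataclasses and YAML (de)serialization."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SQRT3 = math.sqrt(3.0)


class ConfigurationError(ValueError):
    """Raised when a config violates its invariants."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Gate thresholds for the screening stages.

    ``t1`` and ``t2`` split feature points into important / secondary /
    redundant; ``t3`` gates the deep-feature screening. Defaults are the
    best-performing triple (0.5, 0.3, 0.5).
    """

    t1: float = 0.5
    t2: float = 0.3
    t3: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.t2 < self.t1 < 1.0):
            raise ConfigurationError(
                f"thresholds must satisfy 0 < t2 < t1 < 1, got t1={self.t1}, t2={self.t2}"
            )
        if not (0.0 < self.t3 < SQRT3):
            raise ConfigurationError(f"t3 must lie in (0, sqrt(3)), got {self.t3}")


@dataclass(frozen=True)
class ModelConfig:
    """Static architecture hyperparameters.

    ``axis_convention`` binds direction names to normalization axes:
    horizontal -> width, vertical -> height, depth -> channel (the
    default); it is configurable but rarely changed.
    """

    image_size: int = 256
    in_channels: int = 3
    backbone_widths: tuple[int, ...] = (32, 64, 128)
    d_fuse: int = 256
    n_classes: int = 2
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0
    conv1d_kernel: int = 3
    fusion_conv_channels: int = 4
    branch_mean_mode: str = "printed"  # or "branch"
    per_pixel_masks: bool = True
    deep_gate_source: str = "fx"  # or "f1"
    shared_direction_params: bool = False

    def __post_init__(self):
        if self.d_fuse < self.n_classes:
            raise ConfigurationError("d_fuse must be >= n_classes")
        if self.image_size < 8 or self.n_classes < 2:
            raise ConfigurationError("image_size >= 8 and n_classes >= 2 required")
        if any(w <= 0 for w in self.backbone_widths):
            raise ConfigurationError("backbone widths must be positive")
        if self.branch_mean_mode not in ("printed", "branch"):
            raise ConfigurationError(f"unknown branch_mean_mode {self.branch_mean_mode!r}")
        if self.deep_gate_source not in ("fx", "f1"):
            raise ConfigurationError(f"unknown deep_gate_source {self.deep_gate_source!r}")


@dataclass(frozen=True)
class RunConfig:
    """Training-run hyperparameters around a ModelConfig."""

    model: ModelConfig = field(default_factory=ModelConfig)
    optimizer: str = "adam"
    learning_rate: float = 0.0001
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0
    out_dir: str = "runs/default"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


_KNOWN_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}
_KNOWN_RUN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}
_KNOWN_THRESHOLD_KEYS = {f.name for f in dataclasses.fields(ThresholdConfig)}


def _build_model_config(d: dict) -> ModelConfig:
    unknown = set(d) - _KNOWN_MODEL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown model config keys: {sorted(unknown)}")
    d = dict(d)
    if "thresholds" in d and isinstance(d["thresholds"], dict):
        td = d["thresholds"]
        bad = set(td) - _KNOWN_THRESHOLD_KEYS
        if bad:
            raise ConfigurationError(f"unknown threshold keys: {sorted(bad)}")
        d["thresholds"] = ThresholdConfig(**td)
    if "backbone_widths" in d:
        d["backbone_widths"] = tuple(d["backbone_widths"])
    return ModelConfig(**d)


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config, failing fast on unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_RUN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown run config keys: {sorted(unknown)}")
    if "model" in raw and isinstance(raw["model"], dict):
        raw["model"] = _build_model_config(raw["model"])
    return RunConfig(**raw)


def dump_run_config(cfg: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    d["model"]["backbone_widths"] = list(cfg.model.backbone_widths)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
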