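"""Run configuration: YAML/JSON loading with strict key validation.

Omitted fields fall back to the package defaults (the published network and
optimizer settings). Unknown keys are reported by name with their section
path; invalid values are aggregated into one error message.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import yaml

from .model import ModelConfig
from .preprocess import SmoothingConfig
from .synthetic import DEFAULT_CLASS_OVERLAP, DEFAULT_NOISE_SIGMA
from .training import TrainConfig

__all__ = ["GeneratorSettings", "RunConfig", "load_config", "save_config", "stage_seed"]


@dataclass(frozen=True)
class GeneratorSettings:
    """Scalar knobs of the synthetic generator exposed to config files
    (archetype shape parameters stay in code)."""

    samples_per_class_phase: int = 600
    seed: int = 0
    class_overlap: float = DEFAULT_CLASS_OVERLAP
    noise_sigma: float = DEFAULT_NOISE_SIGMA

    def __post_init__(self):
        if self.samples_per_class_phase < 1:
            raise ValueError("samples_per_class_phase must be >= 1")
        if self.class_overlap < 0:
            raise ValueError("class_overlap must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Everything one workflow run needs; sub-configs are individually
    validated by their own dataclasses."""

    data_path: str | None = None
    output_path: str | None = None
    generator: GeneratorSettings = field(default_factory=GeneratorSettings)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    reps: int = 5
    seed: int = 0
    verbosity: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "generator": GeneratorSettings,
    "smoothing": SmoothingConfig,
    "model": ModelConfig,
    "train": TrainConfig,
}
_SCALARS = ("data_path", "output_path", "fractions", "reps", "seed", "verbosity")


def _build_section(cls, mapping: dict, path: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        errors.append(f"unknown key(s) under '{path}': {', '.join(unknown)}")
    kwargs = {k: v for k, v in mapping.items() if k in known}
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as err:
        errors.append(f"invalid value under '{path}': {err}")
        return cls()


def config_from_dict(raw: dict | None) -> RunConfig:
    raw = dict(raw or {})
    errors: list[str] = []
    unknown_top = sorted(set(raw) - set(_SECTIONS) - set(_SCALARS))
    if unknown_top:
        errors.append(f"unknown key(s): {', '.join(unknown_top)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if section is None:
            section = {}
        if not isinstance(section, dict):
            errors.append(f"section '{name}' must be a mapping")
            section = {}
        kwargs[name] = _build_section(cls, section, name, errors)
    for name in _SCALARS:
        if name in raw:
            kwargs[name] = tuple(raw[name]) if name == "fractions" else raw[name]
    if errors:
        raise ValueError("configuration errors:\n  " + "\n  ".join(errors))
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as err:
        raise ValueError(f"configuration errors:\n  {err}") from None


def load_config(path: str) -> RunConfig:
    """Load a YAML (or JSON, a YAML subset) run configuration file."""
    with open(path, encoding="utf-8") as f:
        raw = yaml.safe_load(f)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as f:
        yaml.safe_dump(_clean(cfg.to_dict()), f, sort_keys=False)


def _clean(obj):
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    return obj


def stage_seed(seed: int, stage: str) -> int:
    """Expand one global seed into a named per-stage substream seed."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2**31)
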