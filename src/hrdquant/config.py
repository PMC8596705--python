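"""Run configuration: one YAML file drives the whole pipeline.

A config is a nested structure with sections ``geometry``, ``generator``,
``detection``, ``spatial``, ``stats`` plus top-level ``seed``, ``out_dir``
and ``verbosity``.  Absent keys take their defaults; unknown keys are
rejected by name.  The effective config of every run is echoed to the
output directory so a run can be reproduced from its artefacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .detection import DetectionParams
from .geometry import FieldGeometry
from .synthetic import (
    DEFAULT_AMPLITUDE,
    DEFAULT_BACKGROUND,
    DEFAULT_D_MAX,
    DEFAULT_D_MIN,
    DEFAULT_MIN_SEPARATION,
    DEFAULT_SPECKLE_SHAPE,
)


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Synthetic-slab and cohort generation options."""

    n_per_group: int = 10
    #: optional per-group overrides of the baseline count distribution,
    #: e.g. {"group1": 50.0, "group2": 50.0} for a small smoke field
    baseline_mean: dict | None = None
    baseline_sd: dict | None = None
    d_min: float = DEFAULT_D_MIN
    d_max: float = DEFAULT_D_MAX
    min_separation: float = DEFAULT_MIN_SEPARATION
    amplitude: float = DEFAULT_AMPLITUDE
    background_level: float = DEFAULT_BACKGROUND
    speckle_model: str = "gamma"
    speckle_shape: float = DEFAULT_SPECKLE_SHAPE


@dataclass
class SpatialConfig:
    bin_deg: float = 0.5


@dataclass
class StatsConfig:
    alpha: float = 0.05


@dataclass
class RunConfig:
    seed: int | None = None
    out_dir: str = "results/run"
    verbosity: int = 1
    save_images: bool = True
    geometry: FieldGeometry = field(default_factory=FieldGeometry)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _build(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{section}': {sorted(unknown)}"
        )
    return cls(**data)


_SECTIONS = {
    "geometry": FieldGeometry,
    "generator": GeneratorConfig,
    "detection": DetectionParams,
    "spatial": SpatialConfig,
    "stats": StatsConfig,
}


def config_from_dict(data: dict | None) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            sect = data.pop(name)
            if not isinstance(sect, dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            kwargs[name] = _build(cls, sect, name)
    top_allowed = {"seed", "out_dir", "verbosity", "save_images"}
    unknown = set(data) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs.update(data)
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON, a YAML subset) config file.

    An empty file yields the all-defaults config; unknown keys raise
    :class:`ConfigError` naming the offending keys.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is not None and not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(data)
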