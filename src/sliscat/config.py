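"""Run configuration: a single YAML file covering every pipeline stage.

Lengths carry explicit unit suffixes (``*_mm``, ``*_um``); all angles in
file outputs are degrees.  A single global ``seed`` fans out to per-stage
seeds by stable hashing of stage names, so a stage re-run in isolation
reproduces its in-pipeline randomness.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import DisplayGeometry
from .smoothing import PRESETS, FilterParams


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class AnalysisConfig:
    delta_phi: float = 1.0
    filter_preset: str | None = "sli-1deg"
    filter_cutoff: float | None = None
    filter_width: float | None = None
    prominence_threshold: float = 0.08
    pairing_tolerance_deg: float = 35.0
    reflex_rotation_deg: float = 90.0
    min_radius_px: int = 2

    def filter_params(self) -> FilterParams | None:
        if self.filter_cutoff is not None and self.filter_width is not None:
            return FilterParams(cutoff=self.filter_cutoff, width=self.filter_width)
        if self.filter_preset is None or self.filter_preset == "none":
            return None
        if self.filter_preset not in PRESETS:
            raise ConfigError(
                f"unknown filter preset {self.filter_preset!r}; "
                f"available: {sorted(PRESETS)}"
            )
        return PRESETS[self.filter_preset]


@dataclass
class VisualizationConfig:
    block_size: int = 40
    alpha: float = 0.1
    min_defined_fraction: float = 0.08


@dataclass
class SimulateConfig:
    preset: str = "crossing2"
    phantom_height: int = 8
    phantom_width: int = 8
    noise: bool = True
    shot_scale: float = 50.0
    read_sigma: float = 0.05
    n_shots: int = 1
    vignetting_exponent: float = 4.0


@dataclass
class RunConfig:
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    visualization: VisualizationConfig = field(default_factory=VisualizationConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        n_bins = round(360.0 / self.analysis.delta_phi)
        if abs(n_bins * self.analysis.delta_phi - 360.0) > 1e-9:
            raise ConfigError(
                f"360 must be divisible by delta_phi {self.analysis.delta_phi}"
            )
        self.analysis.filter_params()  # validates preset / parameters

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed below 2**31, stable across sessions and platforms."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


_GEOMETRY_KEYS = {
    "leds_per_side": "leds_per_side",
    "pixel_pitch_mm": "pixel_pitch_mm",
    "source_sample_distance_mm": "source_sample_distance_mm",
    "sample_camera_distance_mm": "sample_camera_distance_mm",
    "kernel_size": "kernel_size",
    "kernels_per_side": "kernels_per_side",
    "object_pixel_size_um": "object_pixel_size_um",
}


def _section(cls, data: dict, name: str):
    section = data.get(name, {}) or {}
    if not isinstance(section, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    valid = {f.name for f in cls.__dataclass_fields__.values()} if hasattr(
        cls, "__dataclass_fields__"
    ) else set()
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    return cls(**section)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    geometry_data = data.get("geometry", {}) or {}
    unknown = set(geometry_data) - set(_GEOMETRY_KEYS)
    if unknown:
        raise ConfigError(f"unknown geometry keys: {sorted(unknown)}")
    geometry = DisplayGeometry(
        **{_GEOMETRY_KEYS[k]: v for k, v in geometry_data.items()}
    )
    return RunConfig(
        geometry=geometry,
        analysis=_section(AnalysisConfig, data, "analysis"),
        visualization=_section(VisualizationConfig, data, "visualization"),
        simulate=_section(SimulateConfig, data, "simulate"),
        seed=int(data.get("seed", 0)),
    )
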