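"""Pipeline configuration: one YAML file, sectioned per stage.

Defaults reproduce the published operating point of the pipeline (frame
rate 6006 fps, x3 upscaling, 12-55 um / 0.7-1 / 1-1.8 / 0-20000 gates,
6 appearances per cell, healthy thresholds 3.15 / 7.7 / 1.46 cells/mL,
15% FISH positivity cutoff).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .cohort import HEALTHY_THRESHOLD_PRESETS
from .detection import DetectionParams
from .gating import GateParams
from .synthetic import SyntheticSpec


@dataclass
class TrackingParams:
    max_displacement: Optional[float] = None  # px; None -> derived from frame width
    max_frame_gap: int = 2
    min_appearances: int = 1


@dataclass
class FishParams:
    fusion_distance: float = 5.0       # px; ~one signal width
    fraction_threshold: float = 15.0   # percent rearranged nuclei


@dataclass
class IoParams:
    pixel_pitch: float = 2.8   # um/px at the sample plane
    fps: float = 6006.0
    blood_volume: Optional[float] = None  # mL; usually from the sidecar


@dataclass
class MarkerParams:
    nucleus_cutoff: float = 9.0  # um
    nc_cutoff: float = 0.5


@dataclass
class PipelineConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    gates: GateParams = field(default_factory=GateParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    fish: FishParams = field(default_factory=FishParams)
    markers: MarkerParams = field(default_factory=MarkerParams)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    io: IoParams = field(default_factory=IoParams)
    cohort_presets: dict[str, float] = field(
        default_factory=lambda: dict(HEALTHY_THRESHOLD_PRESETS))
    seed: int = 0


_SECTIONS = {
    "detection": DetectionParams,
    "gates": GateParams,
    "tracking": TrackingParams,
    "fish": FishParams,
    "markers": MarkerParams,
    "synthetic": SyntheticSpec,
    "io": IoParams,
}

_TUPLE_FIELDS = {
    "diameter", "solidity", "axial_ratio", "intensity_range",
    "diameter_dist", "axial_ratio_dist", "small_diameter_dist",
    "debris_radius_dist", "frame_shape",
}


def _build_section(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in config section {cls.__name__}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict[str, dict[str, Any]] | None = None) -> PipelineConfig:
    """Build a PipelineConfig from defaults, an optional YAML file and overrides."""
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping of sections")
        data = loaded
    if overrides:
        for section, values in overrides.items():
            data.setdefault(section, {}).update(values)

    kwargs: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        kwargs[section] = _build_section(cls, data.get(section, {}) or {})
    if "cohort_presets" in data:
        presets = dict(HEALTHY_THRESHOLD_PRESETS)
        presets.update(data["cohort_presets"])
        kwargs["cohort_presets"] = presets
    kwargs["seed"] = int(data.get("seed", 0))
    unknown = set(data) - set(_SECTIONS) - {"cohort_presets", "seed"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Echo the effective configuration as YAML (tuples become lists)."""
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if hasattr(obj, "tolist"):
            return obj.tolist()
        return obj

    Path(path).write_text(yaml.safe_dump(clean(config), sort_keys=False))
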