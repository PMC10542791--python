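"""Single-document pipeline configuration.

One YAML/JSON document holds every tunable named across the modules, with
the published processing constants as defaults: 1-m voxels in 4-voxel
blocks with a 5-neighbour isolation threshold, 1-m CHM, 50-m TCH, 250-m
map cell, power-law coefficients a = 0.025, b = 1.99, scale = 2, carbon
fraction 0.47, and 1000 Monte Carlo maps for full uncertainty runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .canopy_metrics import AllometricCoefficients
from .synthetic_scene import SceneConfig
from .terrain_model import GroundFilterParams
from .uncertainty import CalibrationUncertainty
from .wall_to_wall import RandomForestConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Every pipeline parameter in one place (YAML round-trippable)."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    ground: GroundFilterParams = field(default_factory=GroundFilterParams)
    allometry: AllometricCoefficients = field(default_factory=AllometricCoefficients)
    forest: RandomForestConfig = field(default_factory=RandomForestConfig)
    calibration: CalibrationUncertainty = field(default_factory=CalibrationUncertainty)
    voxel_size: float = 1.0
    block_extent: int = 4
    min_neighbors: int = 5
    chm_cell: float = 1.0
    tch_cell: float = 50.0
    map_cell: float = 250.0
    min_valid_fraction_tch: float = 0.9
    min_valid_fraction_map: float = 0.5
    carbon_fraction: float = 0.47
    n_uncertainty_maps: int = 1000  # full-run value; tests scale this down


_SECTIONS = ("scene", "ground", "allometry", "forest", "calibration")


def save_config(config: PipelineConfig, path: str | Path) -> None:
    doc: dict = {}
    for f in dataclasses.fields(PipelineConfig):
        value = getattr(config, f.name)
        if f.name in _SECTIONS:
            sub = dataclasses.asdict(value)
            sub.pop("residual_model", None)  # callables are code, not config
            doc[f.name] = sub
        else:
            doc[f.name] = value
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    section_types = {
        "scene": SceneConfig,
        "ground": GroundFilterParams,
        "allometry": AllometricCoefficients,
        "forest": RandomForestConfig,
        "calibration": CalibrationUncertainty,
    }
    for name, typ in section_types.items():
        if name in doc:
            kwargs[name] = typ(**doc.pop(name))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key, value in doc.items():
        if key not in known:
            raise ValueError(f"unknown configuration key {key!r}")
        kwargs[key] = value
    return PipelineConfig(**kwargs)
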