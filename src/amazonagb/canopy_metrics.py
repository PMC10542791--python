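"""Canopy height model, top-of-canopy height and the biomass power law.

Processing order matters and follows the calibration the power law was fit
under: the 1-m CHM (highest normalized return per cell, floored at zero) is
averaged to 50-m top-of-canopy height (TCH) first, and only then converted
to above-ground biomass with

    AGB [kg m^-2] = scale * (a * TCH ** b),  defaults scale=2, a=0.025, b=1.99.

Because b > 1, converting before averaging would inflate the estimate
(Jensen's inequality); the pipeline always averages first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import InvalidConfigError, PipelineError, PointCloud, Raster

__all__ = [
    "AllometricCoefficients",
    "build_chm",
    "aggregate_tch",
    "agb_from_tch",
    "to_mg_ha",
    "regrid_mean",
]

KG_M2_PER_MG_HA = 0.1  # 1 kg m^-2 == 10 Mg ha^-1


@dataclass
class AllometricCoefficients:
    """Coefficients of the TCH -> AGB power law (AGB = scale * a * TCH**b)."""

    a: float = 0.025
    b: float = 1.99
    scale: float = 2.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.scale <= 0:
            raise InvalidConfigError("allometric coefficients must be positive")


def build_chm(
    normalized: PointCloud,
    cell_size: float = 1.0,
    like: Raster | None = None,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> Raster:
    """Canopy height model: highest normalized return per grid cell.

    Values are floored at 0 (negative normalized heights are ground-noise
    artifacts); cells containing no returns are nodata.  Pass ``like`` (for
    instance the DTM) to reuse an existing grid geometry.
    """
    if normalized.n and normalized.z.max() > 120.0:
        warnings.warn(
            "returns above 120 m: cloud may not be height-normalized", stacklevel=2
        )
    if like is not None:
        grid = like.copy_with(np.full(like.values.shape, np.nan))
        grid.cell_size = like.cell_size
    else:
        if origin is None:
            origin = (
                float(np.floor(normalized.x.min())) if normalized.n else 0.0,
                float(np.floor(normalized.y.min())) if normalized.n else 0.0,
            )
        if shape is None:
            n_cols = int(np.ceil((normalized.x.max() - origin[0]) / cell_size)) if normalized.n else 1
            n_rows = int(np.ceil((normalized.y.max() - origin[1]) / cell_size)) if normalized.n else 1
            shape = (max(n_rows, 1), max(n_cols, 1))
        grid = Raster(np.full(shape, np.nan), origin[0], origin[1], cell_size)
    row, col, inside = grid.locate(normalized.x, normalized.y)
    acc = np.full(grid.values.shape, -np.inf)
    np.maximum.at(acc, (row[inside], col[inside]), normalized.z[inside])
    values = np.where(np.isneginf(acc), np.nan, np.maximum(acc, 0.0))
    grid.values = values
    return grid


def aggregate_tch(chm: Raster, target_cell: float = 50.0,
                  min_valid_fraction: float = 0.9) -> Raster:
    """Average 1-m CHM cells into top-of-canopy-height blocks.

    Blocks whose fraction of valid CHM cells falls below
    ``min_valid_fraction`` become nodata rather than biasing TCH low.
    """
    return chm.block_mean(target_cell, min_valid_fraction)


def agb_from_tch(tch: Raster, coeffs: AllometricCoefficients | None = None) -> Raster:
    """Apply the biomass power law per cell; result in kg m^-2, nodata propagates."""
    coeffs = coeffs or AllometricCoefficients()
    vals = tch.values
    finite = np.isfinite(vals)
    if np.any(vals[finite] < 0):
        raise PipelineError("negative TCH encountered; normalize and floor the CHM first")
    with np.errstate(invalid="ignore"):
        agb = coeffs.scale * (coeffs.a * np.power(vals, coeffs.b))
    return tch.copy_with(np.where(finite, agb, np.nan))


def to_mg_ha(agb_kg_m2: Raster) -> Raster:
    """Convert kg m^-2 to Mg ha^-1 (multiply by 10)."""
    return agb_kg_m2.copy_with(agb_kg_m2.values * 10.0)


def regrid_mean(raster: Raster, target_cell: float = 250.0,
                min_valid_fraction: float = 0.5) -> Raster:
    """Block-mean a raster onto a coarser grid (e.g. 50 m -> 250 m).

    The default coverage rule is looser than the CHM->TCH aggregation
    because LiDAR transect edges only partially cover coarse cells.
    """
    return raster.block_mean(target_cell, min_valid_fraction)
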