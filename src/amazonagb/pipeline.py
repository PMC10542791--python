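"""End-to-end orchestration of the transect processing chain.

``process_transect`` runs the standard sequence on one raw cloud:
outlier removal -> ground classification -> 1-m DTM -> height
normalization -> 1-m CHM -> 50-m TCH -> power-law AGB (kg m^-2) ->
Mg ha^-1 -> optional 250-m regrid.  Stage timings and drop counts are
logged to the package logger.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .canopy_metrics import (
    AllometricCoefficients,
    agb_from_tch,
    aggregate_tch,
    build_chm,
    regrid_mean,
    to_mg_ha,
)
from .core import PointCloud, Raster
from .point_cloud import remove_outliers
from .terrain_model import GroundFilterParams, build_dtm, classify_ground, normalize_cloud

__all__ = ["TransectProducts", "process_transect"]

logger = logging.getLogger(__name__)


@dataclass
class TransectProducts:
    """All intermediate and final rasters of one transect run."""

    kept: PointCloud
    removed: PointCloud
    classified: PointCloud
    normalized: PointCloud
    dtm: Raster
    chm: Raster
    tch: Raster
    agb_kg_m2: Raster
    agb_mg_ha: Raster
    agb_250m: Raster | None = None


def process_transect(
    cloud: PointCloud,
    ground_params: GroundFilterParams | None = None,
    coeffs: AllometricCoefficients | None = None,
    chm_cell: float = 1.0,
    tch_cell: float = 50.0,
    map_cell: float | None = 250.0,
    min_valid_fraction_tch: float = 0.9,
    min_valid_fraction_map: float = 0.5,
    voxel_size: float = 1.0,
    block_extent: int = 4,
    min_neighbors: int = 5,
    dtm_origin: tuple[float, float] | None = None,
    dtm_shape: tuple[int, int] | None = None,
) -> TransectProducts:
    """Run the full LiDAR-to-biomass chain on one transect cloud.

    ``map_cell=None`` skips the coarse regrid (useful when the transect
    extent is not an exact multiple of the map cell).
    """
    t0 = time.perf_counter()
    kept, removed = remove_outliers(cloud, voxel_size, block_extent, min_neighbors)
    logger.info("outlier filter: removed %d of %d returns (%.1fs)",
                removed.n, cloud.n, time.perf_counter() - t0)

    t0 = time.perf_counter()
    classified = classify_ground(kept, ground_params)
    n_ground = int((classified.classification == 2).sum())
    logger.info("ground filter: %d ground returns (%.1fs)", n_ground, time.perf_counter() - t0)

    t0 = time.perf_counter()
    if dtm_origin is None:
        # grid must cover every kept return, not just the ground subset
        dtm_origin = (float(np.floor(kept.x.min())), float(np.floor(kept.y.min())))
    if dtm_shape is None:
        dtm_shape = (
            int(np.ceil((kept.y.max() - dtm_origin[1]) / chm_cell)),
            int(np.ceil((kept.x.max() - dtm_origin[0]) / chm_cell)),
        )
    dtm = build_dtm(classified, cell_size=chm_cell, origin=dtm_origin, shape=dtm_shape)
    normalized = normalize_cloud(kept, dtm)
    logger.info("DTM + normalization (%.1fs)", time.perf_counter() - t0)

    t0 = time.perf_counter()
    chm = build_chm(normalized, like=dtm)
    tch = aggregate_tch(chm, tch_cell, min_valid_fraction_tch)
    agb = agb_from_tch(tch, coeffs)
    agb_mg = to_mg_ha(agb)
    agb_250 = None
    if map_cell is not None:
        try:
            agb_250 = regrid_mean(agb_mg, map_cell, min_valid_fraction_map)
        except Exception as exc:  # noqa: BLE001 - non-divisible extents are expected
            logger.warning("skipping %gm regrid: %s", map_cell, exc)
    logger.info("CHM/TCH/AGB (%.1fs)", time.perf_counter() - t0)
    return TransectProducts(
        kept=kept, removed=removed, classified=classified, normalized=normalized,
        dtm=dtm, chm=chm, tch=tch, agb_kg_m2=agb, agb_mg_ha=agb_mg, agb_250m=agb_250,
    )
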