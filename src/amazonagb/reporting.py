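"""Carbon conversion, reference-map comparison and map summaries.

Final map products are summarized cell-weighted over valid cells with the
population (n) standard-deviation convention; the comparison against a
reference map nearest-resamples the reference onto the candidate grid and
reports candidate minus reference (negative = candidate lower).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InvalidConfigError, PipelineError, Raster
from .wall_to_wall import resample_covariate

__all__ = ["MapSummary", "agb_to_carbon", "compare_maps", "summarize_map"]


@dataclass
class MapSummary:
    """Cell-weighted summary statistics of a map layer (Mg ha^-1)."""

    max: float
    mean: float
    sd: float               # population (n) convention
    valid_cell_count: int
    nodata_cell_count: int


def agb_to_carbon(agb: Raster, fraction: float = 0.47) -> Raster:
    """Convert biomass (Mg ha^-1) to carbon by the carbon fraction."""
    if not 0.0 < fraction <= 1.0:
        raise InvalidConfigError("carbon fraction must lie in (0, 1]")
    return agb.copy_with(agb.values * fraction)


def compare_maps(
    candidate: Raster,
    reference: Raster,
    mask: Raster,
    reference_resampling: str = "nearest",
) -> Raster:
    """Candidate minus reference, restricted to mask == 1.

    The reference is nearest-resampled onto the candidate grid first; the
    mask must be binary on the candidate grid (1 = compare, anything else =
    exclude).  Negative output means the candidate is lower than the
    reference.
    """
    if reference_resampling != "nearest":
        raise InvalidConfigError("only nearest reference resampling is supported")
    if not mask.same_grid(candidate):
        raise PipelineError("mask must be on the candidate grid")
    m = mask.values == 1
    if not m.any():
        raise PipelineError("empty comparison mask")
    ref_on_cand = resample_covariate(reference, candidate, method="nearest")
    diff = candidate.values - ref_on_cand.values
    return candidate.copy_with(np.where(m, diff, np.nan))


def summarize_map(raster: Raster, mask: Raster | None = None) -> MapSummary:
    """Max / mean / population SD over valid (optionally masked) cells."""
    values = raster.values
    valid = np.isfinite(values)
    if mask is not None:
        if not mask.same_grid(raster):
            raise PipelineError("mask must share the raster grid")
        valid &= mask.values == 1
    if not valid.any():
        raise PipelineError("no valid cells to summarize")
    v = values[valid]
    return MapSummary(
        max=float(v.max()),
        mean=float(v.mean()),
        sd=float(v.std()),  # ddof=0: population convention
        valid_cell_count=int(valid.sum()),
        nodata_cell_count=int(values.size - valid.sum()),
    )
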