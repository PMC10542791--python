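"""Field-plot biomass, plot-level LiDAR estimates and the validation test.

Plot AGB is the sum of individual-stem biomass (kg) over the plot area
(m^2).  Stem biomass comes from an :class:`AllometryRegistry` mapping each
growth form (tree, palm, liana) to a published-style allometric function of
DBH (cm), height (m) and wood density (g cm^-3).  The shipped defaults are
documented stand-ins — a pantropical moist-forest D-H-rho power law for
trees and D-based power laws for palms and lianas — and are fully
overridable; nothing downstream depends on their specific coefficients.

The validation comparison crops the transect cloud to each plot polygon,
runs the plot through the normal CHM -> TCH -> power-law chain, and tests
field vs LiDAR AGB with the Wilcoxon–Mann–Whitney rank-sum test (both the
U statistic and the rank-sum W of the first sample are reported, since
software conventions differ).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import shapely
from scipy.stats import mannwhitneyu
from shapely.geometry import Polygon

from .canopy_metrics import AllometricCoefficients, build_chm
from .core import InvalidConfigError, PipelineError, PointCloud, Raster
from .terrain_model import normalize_cloud

__all__ = [
    "TreeRecord",
    "FieldPlot",
    "AllometryRegistry",
    "default_registry",
    "stem_agb",
    "stem_agb_table",
    "plot_agb",
    "clip_cloud",
    "lidar_plot_agb",
    "PlotEstimate",
    "wilcoxon_rank_sum",
    "WilcoxonResult",
    "validate_against_field",
    "ValidationReport",
]

GROWTH_FORMS = ("tree", "palm", "liana")


@dataclass
class TreeRecord:
    """One stem: DBH in cm at 1.3 m, total height in m, wood density in g cm^-3."""

    dbh: float
    height: float
    wood_density: float
    growth_form: str = "tree"

    def __post_init__(self) -> None:
        if self.dbh <= 0 or self.height <= 0:
            raise InvalidConfigError("dbh and height must be positive")
        if not 0.1 <= self.wood_density <= 1.2:
            raise InvalidConfigError("wood density outside plausible range 0.1–1.2 g cm^-3")
        if self.growth_form not in GROWTH_FORMS:
            raise InvalidConfigError(f"unknown growth form {self.growth_form!r}")


@dataclass
class FieldPlot:
    """Georeferenced inventory plot with its individual stem records."""

    plot_id: str
    polygon: Polygon
    stems: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["dbh", "height", "wood_density", "growth_form"]))
    area: float | None = None

    def __post_init__(self) -> None:
        if self.area is None:
            self.area = float(self.polygon.area)
        if self.area <= 0:
            raise InvalidConfigError("plot area must be positive")
        if abs(self.area - self.polygon.area) > 1e-3 * self.area:
            raise InvalidConfigError(
                f"plot {self.plot_id}: stated area {self.area} differs from polygon "
                f"area {self.polygon.area} by more than 0.1%"
            )


class AllometryRegistry:
    """Per-growth-form allometric functions (dbh, height, wood_density) -> kg.

    Functions must be vectorizable over numpy arrays.  Each entry carries a
    citation tag so reports can state which equation produced a number.
    """

    def __init__(self) -> None:
        self._funcs: dict[str, tuple[Callable, str]] = {}

    def register(self, growth_form: str, func: Callable, citation: str = "user") -> None:
        self._funcs[growth_form] = (func, citation)

    def get(self, growth_form: str) -> tuple[Callable, str]:
        try:
            return self._funcs[growth_form]
        except KeyError:
            raise PipelineError(
                f"no allometric equation registered for growth form {growth_form!r}"
            ) from None

    @property
    def growth_forms(self) -> tuple[str, ...]:
        return tuple(self._funcs)


def default_registry() -> AllometryRegistry:
    """Registry with documented stand-in equations for the three growth forms."""
    reg = AllometryRegistry()
    reg.register(
        "tree",
        lambda dbh, height, rho: 0.0673 * (rho * dbh**2 * height) ** 0.976,
        citation="pantropical moist-forest D-H-rho power law (stand-in)",
    )
    reg.register(
        "palm",
        lambda dbh, height, rho: np.exp(-3.3488 + 2.7483 * np.log(dbh)),
        citation="D-based palm power law (stand-in)",
    )
    reg.register(
        "liana",
        lambda dbh, height, rho: np.exp(-1.484 + 2.657 * np.log(dbh)),
        citation="D-based liana power law (stand-in)",
    )
    return reg


def stem_agb(record: TreeRecord, registry: AllometryRegistry) -> float:
    """Above-ground biomass (kg) of a single stem."""
    func, _ = registry.get(record.growth_form)
    return float(func(record.dbh, record.height, record.wood_density))


def stem_agb_table(stems: pd.DataFrame, registry: AllometryRegistry) -> np.ndarray:
    """Vectorized stem AGB (kg) for a stem table with the TreeRecord columns."""
    out = np.empty(len(stems))
    forms = stems["growth_form"].to_numpy()
    for form in np.unique(forms):
        func, _ = registry.get(str(form))
        sel = forms == form
        out[sel] = func(
            stems["dbh"].to_numpy()[sel],
            stems["height"].to_numpy()[sel],
            stems["wood_density"].to_numpy()[sel],
        )
    return out


def plot_agb(plot: FieldPlot, registry: AllometryRegistry) -> float:
    """Field-plot AGB in kg m^-2: total stem biomass over plot area."""
    if len(plot.stems) == 0:
        warnings.warn(f"plot {plot.plot_id}: empty stem list, AGB = 0", stacklevel=2)
        return 0.0
    return float(stem_agb_table(plot.stems, registry).sum() / plot.area)


def clip_cloud(cloud: PointCloud, polygon: Polygon) -> PointCloud:
    """Returns inside or on the boundary of the polygon (closed polygon)."""
    if not polygon.is_valid:
        raise PipelineError("clip polygon is invalid (self-intersecting?)")
    if cloud.n == 0:
        return cloud.subset(np.zeros(0, dtype=bool))
    mask = shapely.intersects_xy(polygon, cloud.x, cloud.y)
    return cloud.subset(mask)


@dataclass
class PlotEstimate:
    """LiDAR-derived plot AGB with its intermediate quantities."""

    agb_kg_m2: float
    tch_m: float
    n_returns: int
    low_coverage: bool


def lidar_plot_agb(
    cloud: PointCloud,
    plot: FieldPlot,
    dtm: Raster,
    coeffs: AllometricCoefficients | None = None,
    chm_cell: float = 1.0,
) -> PlotEstimate:
    """Estimate plot AGB (kg m^-2) from the LiDAR cloud over the plot.

    Crops the cloud to the plot polygon, normalizes against the transect
    DTM, builds a 1-m CHM on the DTM-aligned grid, averages CHM cells whose
    centres fall inside the polygon into a plot-level TCH, and applies the
    biomass power law.  Fewer than one return per 4 m^2 raises a
    low-coverage flag on the result (not an error).
    """
    coeffs = coeffs or AllometricCoefficients()
    clipped = clip_cloud(cloud, plot.polygon)
    low = clipped.n < plot.area / 4.0
    if clipped.n == 0:
        return PlotEstimate(0.0, 0.0, 0, True)
    normalized = normalize_cloud(clipped, dtm)
    minx, miny, maxx, maxy = plot.polygon.bounds
    origin = (
        dtm.origin_x + np.floor((minx - dtm.origin_x) / chm_cell) * chm_cell,
        dtm.origin_y + np.floor((miny - dtm.origin_y) / chm_cell) * chm_cell,
    )
    shape = (
        int(np.ceil((maxy - origin[1]) / chm_cell)),
        int(np.ceil((maxx - origin[0]) / chm_cell)),
    )
    chm = build_chm(normalized, cell_size=chm_cell, origin=origin, shape=shape)
    xc, yc = chm.cell_centers()
    gx, gy = np.meshgrid(xc, yc)
    in_plot = shapely.intersects_xy(plot.polygon, gx.ravel(), gy.ravel()).reshape(gx.shape)
    cells = chm.values[in_plot]
    cells = cells[np.isfinite(cells)]
    tch = float(cells.mean()) if cells.size else 0.0
    agb = coeffs.scale * coeffs.a * tch**coeffs.b
    return PlotEstimate(float(agb), tch, clipped.n, bool(low))


# ---------------------------------------------------------------------------
# Wilcoxon–Mann–Whitney rank-sum test
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    u: float           # Mann–Whitney U of the first sample
    w: float           # rank-sum of the first sample (U + n_x (n_x + 1) / 2)
    p_two_sided: float
    method: str        # "exact" or "asymptotic"


def wilcoxon_rank_sum(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon–Mann–Whitney test.

    Exact null enumeration when ``n_x * n_y <= 400`` and the pooled sample
    is tie-free; otherwise the normal approximation with tie-corrected
    variance and continuity correction.  Both the U statistic and the
    rank-sum convention W are reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InvalidConfigError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both samples; p = 1", stacklevel=2)
        u = x.size * y.size / 2.0
        return WilcoxonResult(u, u + x.size * (x.size + 1) / 2.0, 1.0, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if x.size == y.size and np.array_equal(np.sort(x), np.sort(y)):
        # perfectly matched samples sit at the centre of the null: p = 1
        u = x.size * y.size / 2.0
        return WilcoxonResult(u, u + x.size * (x.size + 1) / 2.0, 1.0, "degenerate")
    exact = (x.size * y.size <= 400) and not has_ties
    res = mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u = float(res.statistic)
    w = u + x.size * (x.size + 1) / 2.0
    return WilcoxonResult(u, w, float(res.pvalue), "exact" if exact else "asymptotic")


# ---------------------------------------------------------------------------
# Field validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Paired field vs LiDAR plot AGB with the rank-sum comparison."""

    table: pd.DataFrame          # plot_id, field_agb_kg_m2, lidar_agb_kg_m2, tch_m
    field_mean: float
    lidar_mean: float
    wilcoxon: WilcoxonResult

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_plots": int(len(self.table)),
            "field_mean_kg_m2": self.field_mean,
            "lidar_mean_kg_m2": self.lidar_mean,
            "wilcoxon_u": self.wilcoxon.u,
            "wilcoxon_w": self.wilcoxon.w,
            "p_two_sided": self.wilcoxon.p_two_sided,
            "method": self.wilcoxon.method,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def validate_against_field(
    plots: list[FieldPlot],
    clouds: "PointCloud | Mapping[str, PointCloud]",
    registry: AllometryRegistry,
    dtm: Raster,
    coeffs: AllometricCoefficients | None = None,
) -> ValidationReport:
    """Compare field-inventory AGB against LiDAR-derived AGB plot by plot.

    ``clouds`` is either one transect cloud covering every plot or a
    mapping of plot id to a per-plot cloud; missing ids raise with the
    orphan list.
    """
    if len(plots) < 2:
        raise InvalidConfigError("validation needs at least 2 plots")
    if isinstance(clouds, PointCloud):
        cloud_of = {p.plot_id: clouds for p in plots}
    else:
        orphans = [p.plot_id for p in plots if p.plot_id not in clouds]
        if orphans:
            raise PipelineError(f"plots without matching clouds: {orphans}")
        cloud_of = dict(clouds)
    rows = []
    for plot in plots:
        est = lidar_plot_agb(cloud_of[plot.plot_id], plot, dtm, coeffs)
        rows.append(
            {
                "plot_id": plot.plot_id,
                "field_agb_kg_m2": plot_agb(plot, registry),
                "lidar_agb_kg_m2": est.agb_kg_m2,
                "tch_m": est.tch_m,
                "low_coverage": est.low_coverage,
            }
        )
    table = pd.DataFrame(rows)
    wt = wilcoxon_rank_sum(table["field_agb_kg_m2"], table["lidar_agb_kg_m2"])
    return ValidationReport(
        table=table,
        field_mean=float(table["field_agb_kg_m2"].mean()),
        lidar_mean=float(table["lidar_agb_kg_m2"].mean()),
        wilcoxon=wt,
    )
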