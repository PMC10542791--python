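"""Synthetic transect-scale forest scenes with complete ground truth.

The generator emulates the acquisition design the pipeline was built for —
long rectangular transects (12.5 km x 300 m in the field campaign,
truncatable for tests) flown at about four returns per square metre over
undulating terrain with a closed tropical canopy — and produces everything
a downstream stage could be scored against: the true terrain surface, the
individual tree list, the simulated return cloud with per-return truth
labels, true biomass rasters, inventory plots with stem records, and a
250-m covariate stack statistically coupled to true biomass.

Scene model in brief:

* terrain: low-pass-filtered Gaussian random field, rescaled so the
  peak-to-trough range equals the configured relief amplitude;
* stand: inhomogeneous Poisson stem process whose intensity is a smooth
  log-normal field (this spatial heterogeneity is what the wall-to-wall
  extrapolation later recovers); heights Gaussian, DBH a power of height
  with log-normal scatter, wood density Gaussian;
* crowns: cone-capped cylinders — the canopy surface is the tree height
  over the inner half of the crown radius and tapers linearly to 75% of it
  at the edge;
* returns: per 1-m column a Poisson number of returns; under canopy a
  return reflects from the crown with fixed interception probability, at a
  vertically uniform depth within the crown mantle, otherwise from the
  ground with Gaussian vertical noise; isolated noise points are injected high above the canopy
  in distinct 4-m voxel blocks so each has zero in-block neighbours.

Every product is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter, maximum_filter
from shapely import affinity
from shapely.geometry import Polygon, box

from .core import CoRegistrationError, InvalidConfigError, PipelineError, PointCloud, Raster
from .field_calibration import AllometryRegistry, FieldPlot, default_registry, stem_agb_table
from .wall_to_wall import CovariateStack, summarize_time_series

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "TRUTH_GROUND",
    "TRUTH_CROWN",
    "TRUTH_OUTLIER",
    "generate_terrain",
    "generate_stand",
    "simulate_point_cloud",
    "uniform_canopy_cloud",
    "true_agb_raster",
    "generate_covariates",
    "transect_polygon",
    "generate_plots",
    "generate_scene",
]

# Per-return truth codes carried alongside simulated clouds.
TRUTH_GROUND = 0
TRUTH_CROWN = 1
TRUTH_OUTLIER = 2


@dataclass
class SceneConfig:
    """Parameters of a synthetic transect scene.

    Defaults reproduce the acquisition design at a test-friendly extent:
    4 returns m^-2 over a 500 m x 300 m window (the full 12.5 km x 300 m
    transect remains a config choice).  ``dbh_scale`` is calibrated so the
    stem-allometry biomass of the synthetic stand agrees in the mean with
    the canopy-height power law — the condition under which the field
    validation is consistent by construction.
    """

    extent_length: float = 500.0            # m, along x
    extent_width: float = 300.0             # m, along y
    terrain_relief_amplitude: float = 12.0  # m peak-to-trough
    terrain_correlation_length: float = 150.0  # m
    terrain_cell_size: float = 1.0          # m
    base_elevation: float = 100.0           # m, mean terrain elevation
    stem_density: float = 500.0             # stems ha^-1
    height_mean: float = 24.0               # m
    height_sd: float = 6.0                  # m, total (patch + within-patch)
    height_within_sd: float = 0.5           # m, tree-to-tree scatter within a patch
    height_correlation: float = 80.0        # m, patch scale of the height field
    min_height: float = 3.0                 # m, truncation of the height draw
    dbh_height_coupling: float = 1.3        # DBH ~ dbh_scale * H ** coupling
    dbh_scale: float = 0.377                # cm m^-coupling (calibrated, see docs)
    dbh_scatter_sd: float = 0.10            # log-normal SD of DBH around the coupling
    wood_density_mean: float = 0.62         # g cm^-3
    wood_density_sd: float = 0.08
    point_density: float = 4.0              # returns m^-2
    outlier_count: int = 30
    ground_noise_sd: float = 0.15           # m, total vertical scatter of ground echoes
    ground_ranging_sd: float = 0.03         # m, per-return ranging noise component
    ground_roughness_correlation: float = 12.0  # m, scale of the micro-relief component
    canopy_interception: float = 0.70       # crown-return probability under canopy
    crown_mantle_depth: float = 1.2         # m, return depth range into the crown
    density_field_cv: float = 0.20          # spatial CV of the stem-intensity field
    density_field_correlation: float = 400.0  # m
    n_composites: int = 23                  # one year of 16-day vegetation composites
    ndvi_noise_sd: float = 0.03
    evi_noise_sd: float = 0.03
    hv_noise_sd: float = 0.6                # dB
    hh_noise_sd: float = 0.8                # dB
    seed: int = 0

    def validate(self) -> None:
        if self.extent_length <= 0 or self.extent_width <= 0:
            raise InvalidConfigError("extent must be positive")
        if self.point_density <= 0:
            raise InvalidConfigError("point density must be positive")
        if self.stem_density < 0:
            raise InvalidConfigError("stem density must be non-negative")
        if self.terrain_correlation_length <= 0 or self.terrain_cell_size <= 0:
            raise InvalidConfigError("terrain scales must be positive")
        if self.terrain_relief_amplitude < 0:
            raise InvalidConfigError("relief amplitude must be non-negative")


@dataclass
class SyntheticScene:
    """A generated scene with its complete ground truth."""

    config: SceneConfig
    true_dtm: Raster
    tree_list: pd.DataFrame
    cloud: PointCloud | None
    truth: np.ndarray | None                 # per-return TRUTH_* codes
    true_agb_50m: Raster | None = None       # kg m^-2
    true_agb_250m: Raster | None = None      # kg m^-2
    covariates: CovariateStack | None = None
    plots: list[FieldPlot] = field(default_factory=list)


def _rng(config: SceneConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------

def generate_terrain(config: SceneConfig) -> Raster:
    """Smooth seeded random elevation surface.

    Recipe: white Gaussian noise on the terrain grid, Gaussian low-pass
    filter with sigma = correlation_length / (2 * cell), then min-max
    rescaled so the peak-to-trough range equals the relief amplitude and
    the mean sits near ``base_elevation``.  Zero amplitude gives a constant
    surface.  Deterministic given the seed.
    """
    config.validate()
    cell = config.terrain_cell_size
    n_cols = int(round(config.extent_length / cell))
    n_rows = int(round(config.extent_width / cell))
    if n_cols < 1 or n_rows < 1:
        raise InvalidConfigError("extent smaller than one terrain cell")
    if config.terrain_relief_amplitude == 0:
        values = np.full((n_rows, n_cols), config.base_elevation)
        return Raster(values, 0.0, 0.0, cell)
    rng = _rng(config, 1)
    noise = rng.standard_normal((n_rows, n_cols))
    sigma = config.terrain_correlation_length / (2.0 * cell)
    smooth = gaussian_filter(noise, sigma=sigma, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    values = (smooth - lo) / (hi - lo) * config.terrain_relief_amplitude
    values += config.base_elevation - values.mean()
    return Raster(values, 0.0, 0.0, cell)


# ---------------------------------------------------------------------------
# Stand
# ---------------------------------------------------------------------------

def generate_stand(config: SceneConfig, terrain: Raster) -> pd.DataFrame:
    """Tree list with stem positions, sizes and growth forms.

    Stems follow a Poisson process whose intensity is modulated by a
    smooth log-normal field (mean 1, CV ``density_field_cv``), which gives
    the landscape the biomass heterogeneity the extrapolation model is
    later asked to recover.
    """
    config.validate()
    cols = ["x", "y", "height", "dbh", "wood_density", "growth_form", "crown_radius"]
    if config.stem_density == 0:
        return pd.DataFrame(columns=cols)
    rng = _rng(config, 2)
    cell = 25.0  # intensity-field resolution, m
    nbx = max(int(math.ceil(config.extent_length / cell)), 1)
    nby = max(int(math.ceil(config.extent_width / cell)), 1)
    if config.density_field_cv > 0:
        sigma_ln = math.sqrt(math.log(1.0 + config.density_field_cv**2))
        raw = gaussian_filter(
            rng.standard_normal((nby, nbx)),
            sigma=config.density_field_correlation / (2.0 * cell),
            mode="reflect",
        )
        sd = raw.std()
        z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
        intensity = np.exp(sigma_ln * z - 0.5 * sigma_ln**2)
    else:
        intensity = np.ones((nby, nbx))
    # clip partial edge cells to the true extent
    wx = np.minimum(cell, config.extent_length - np.arange(nbx) * cell)
    wy = np.minimum(cell, config.extent_width - np.arange(nby) * cell)
    areas = np.outer(wy, wx)
    lam = config.stem_density / 1e4 * intensity * areas
    counts = rng.poisson(lam)
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=cols)
    by, bx = np.nonzero(counts)
    reps = counts[by, bx]
    cx = np.repeat(bx, reps)
    cy = np.repeat(by, reps)
    x = cx * cell + rng.random(total) * np.repeat(wx[bx], reps)
    y = cy * cell + rng.random(total) * np.repeat(wy[by], reps)
    # canopy height is spatially autocorrelated: a smooth patch-scale mean
    # field plus small tree-to-tree scatter (total marginal SD = height_sd)
    within = min(config.height_within_sd, config.height_sd)
    between = math.sqrt(max(config.height_sd**2 - within**2, 0.0))
    if between > 0:
        hcell = 10.0
        nhx = max(int(math.ceil(config.extent_length / hcell)), 1)
        nhy = max(int(math.ceil(config.extent_width / hcell)), 1)
        raw = gaussian_filter(
            rng.standard_normal((nhy, nhx)),
            sigma=config.height_correlation / (2.0 * hcell),
            mode="reflect",
        )
        sd = raw.std()
        hfield = config.height_mean + ((raw - raw.mean()) / sd * between if sd > 0 else 0.0)
        hx = np.clip((x / hcell).astype(int), 0, nhx - 1)
        hy = np.clip((y / hcell).astype(int), 0, nhy - 1)
        local_mean = hfield[hy, hx]
    else:
        local_mean = np.full(total, config.height_mean)
    height = np.maximum(
        local_mean + rng.normal(0.0, within, total), config.min_height
    )
    dbh = config.dbh_scale * height**config.dbh_height_coupling * np.exp(
        rng.normal(0.0, config.dbh_scatter_sd, total)
    )
    rho = np.clip(
        rng.normal(config.wood_density_mean, config.wood_density_sd, total), 0.3, 0.95
    )
    form = rng.choice(["tree", "palm", "liana"], size=total, p=[0.90, 0.06, 0.04])
    crown_radius = 1.5 + 0.18 * height
    return pd.DataFrame(
        {
            "x": x, "y": y, "height": height, "dbh": dbh,
            "wood_density": rho, "growth_form": form, "crown_radius": crown_radius,
        }
    )


def _canopy_surface(terrain_like: Raster, trees: pd.DataFrame, cell: float = 1.0,
                    extent: tuple[float, float] | None = None) -> Raster:
    """Height-above-ground of the canopy surface on a 1-m grid (0 in gaps).

    Cone-capped cylinder crowns: surface height equals the tree height over
    the inner half radius and tapers linearly to 0.75 H at the crown edge;
    overlapping crowns take the maximum.
    """
    if extent is None:
        extent = (terrain_like.width, terrain_like.height)
    n_cols = int(round(extent[0] / cell))
    n_rows = int(round(extent[1] / cell))
    surf = np.zeros((n_rows, n_cols))
    xs = trees["x"].to_numpy()
    ys = trees["y"].to_numpy()
    hs = trees["height"].to_numpy()
    rs = trees["crown_radius"].to_numpy()
    xc = (np.arange(n_cols) + 0.5) * cell
    yc = (np.arange(n_rows) + 0.5) * cell
    for x, y, h, r in zip(xs, ys, hs, rs):
        c0 = max(int((x - r) / cell), 0)
        c1 = min(int((x + r) / cell) + 1, n_cols)
        r0 = max(int((y - r) / cell), 0)
        r1 = min(int((y + r) / cell) + 1, n_rows)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xc[c0:c1] - x
        dy = yc[r0:r1] - y
        d = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2)
        inside = d <= r
        taper = np.where(d <= 0.5 * r, h, h * (1.0 - 0.1 * (d / r - 0.5)))
        block = surf[r0:r1, c0:c1]
        np.maximum(block, np.where(inside, taper, 0.0), out=block)
    # morphological closing of metre-scale gaps: dense tropical canopies are
    # a continuous mantle, not isolated cones; max preserves apex heights
    surf = maximum_filter(surf, size=5)
    return Raster(surf, 0.0, 0.0, cell)


def simulate_point_cloud(
    terrain: Raster, trees: pd.DataFrame, config: SceneConfig
) -> tuple[PointCloud, np.ndarray]:
    """Simulate the discrete-return cloud over a stand.

    Returns ``(cloud, truth)`` where ``truth`` holds the per-return
    TRUTH_GROUND / TRUTH_CROWN / TRUTH_OUTLIER codes.  Injected noise
    points are placed 10–100 m above the canopy in pairwise-distinct 4-m
    voxel blocks, so each has zero in-block neighbours by construction.
    """
    config.validate()
    if len(trees):
        inside = (
            (trees["x"] >= 0) & (trees["x"] <= config.extent_length)
            & (trees["y"] >= 0) & (trees["y"] <= config.extent_width)
        )
        if not inside.all():
            raise PipelineError(
                f"{int((~inside).sum())} trees fall outside the scene extent"
            )
    rng = _rng(config, 3)
    surface = _canopy_surface(
        terrain, trees, cell=1.0, extent=(config.extent_length, config.extent_width)
    )
    n_rows, n_cols = surface.values.shape
    counts = rng.poisson(config.point_density, size=n_rows * n_cols)
    total = int(counts.sum())
    cell_ids = np.repeat(np.arange(n_rows * n_cols), counts)
    rows, cols = np.divmod(cell_ids, n_cols)
    x = cols + rng.random(total)
    y = rows + rng.random(total)
    trow, tcol, _ = terrain.locate(x, y)
    trow = np.clip(trow, 0, terrain.n_rows - 1)
    tcol = np.clip(tcol, 0, terrain.n_cols - 1)
    ground_z = terrain.values[trow, tcol]
    h_loc = surface.values[rows, cols]
    under_canopy = h_loc > 0
    is_crown = under_canopy & (rng.random(total) < config.canopy_interception)
    z = np.empty(total)
    n_ground = int((~is_crown).sum())
    # ground scatter = spatially correlated micro-relief + per-return ranging
    # noise; the marginal SD is ground_noise_sd but the within-column band is
    # thin, as on real surfaces
    ranging = min(config.ground_ranging_sd, config.ground_noise_sd)
    rough_sd = math.sqrt(max(config.ground_noise_sd**2 - ranging**2, 0.0))
    if rough_sd > 0:
        raw = gaussian_filter(
            rng.standard_normal((n_rows, n_cols)),
            sigma=config.ground_roughness_correlation / 2.0,
            mode="reflect",
        )
        rsd = raw.std()
        micro = (raw - raw.mean()) / rsd * rough_sd if rsd > 0 else raw * 0.0
    else:
        micro = np.zeros((n_rows, n_cols))
    z[~is_crown] = (
        ground_z[~is_crown]
        + micro[rows[~is_crown], cols[~is_crown]]
        + rng.normal(0.0, ranging, n_ground)
    )
    # return depth below the canopy surface: vertically uniform within the
    # crown mantle (discrete-return sensors rarely record mid-crown echoes)
    cap = np.minimum(config.crown_mantle_depth, 0.5 * h_loc[is_crown])
    depth = rng.random(int(is_crown.sum())) * cap
    z[is_crown] = ground_z[is_crown] + h_loc[is_crown] - depth
    truth = np.where(is_crown, TRUTH_CROWN, TRUTH_GROUND).astype(np.uint8)

    if config.outlier_count > 0:
        z_top = float((terrain.values[trow, tcol] + h_loc).max()) if total else 0.0
        ox, oy, oz = _isolated_outliers(rng, config, z_top)
        x = np.concatenate([x, ox])
        y = np.concatenate([y, oy])
        z = np.concatenate([z, oz])
        truth = np.concatenate(
            [truth, np.full(config.outlier_count, TRUTH_OUTLIER, dtype=np.uint8)]
        )
    rn = rng.integers(1, 4, size=x.size).astype(np.uint8)
    return PointCloud(x, y, z, rn), truth


def _isolated_outliers(
    rng: np.random.Generator, config: SceneConfig, z_top: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise points above the canopy occupying pairwise-distinct 4-m blocks."""
    need = config.outlier_count
    xs: list[float] = []
    ys: list[float] = []
    zs: list[float] = []
    used: set[tuple[int, int, int]] = set()
    guard = 0
    while len(xs) < need:
        guard += 1
        if guard > 100 * need:
            raise PipelineError("could not place isolated outliers in distinct blocks")
        px = rng.random() * config.extent_length
        py = rng.random() * config.extent_width
        pz = z_top + 10.0 + rng.random() * 90.0
        key = (int(px // 4), int(py // 4), int(pz // 4))
        if key in used:
            continue
        used.add(key)
        xs.append(px)
        ys.append(py)
        zs.append(pz)
    return np.array(xs), np.array(ys), np.array(zs)


def uniform_canopy_cloud(
    extent_length: float = 200.0,
    extent_width: float = 200.0,
    tch: float = 25.0,
    base_elevation: float = 100.0,
) -> PointCloud:
    """Noiseless uniform-canopy fixture for calibration-closure checks.

    Every 1-m column carries exactly one ground echo at the (flat) terrain
    elevation and one crown echo at ``tch`` above it, so the pipeline's
    plot-level TCH equals ``tch`` up to CHM discretization.
    """
    n_cols = int(round(extent_length))
    n_rows = int(round(extent_width))
    xc = np.tile((np.arange(n_cols) + 0.5), n_rows)
    yc = np.repeat((np.arange(n_rows) + 0.5), n_cols)
    x = np.concatenate([xc, xc])
    y = np.concatenate([yc, yc])
    z = np.concatenate(
        [np.full(xc.size, base_elevation), np.full(xc.size, base_elevation + tch)]
    )
    return PointCloud(x, y, z)


# ---------------------------------------------------------------------------
# Truth rasters, covariates, geometry
# ---------------------------------------------------------------------------

def true_agb_raster(
    trees: pd.DataFrame,
    grid_size: float,
    allometry: AllometryRegistry | None = None,
    extent: tuple[float, float] | None = None,
) -> Raster:
    """Per-cell stem biomass density (kg m^-2) on a ``grid_size`` grid.

    Cell value = sum of individual stem AGB (kg) over the cell / cell area
    (m^2); the cell-summed total is conserved against the stem-summed total
    exactly.
    """
    allometry = allometry or default_registry()
    if extent is None:
        if len(trees) == 0:
            raise InvalidConfigError("cannot infer extent from an empty tree list")
        extent = (
            math.ceil(trees["x"].max() / grid_size) * grid_size,
            math.ceil(trees["y"].max() / grid_size) * grid_size,
        )
    n_cols = int(round(extent[0] / grid_size))
    n_rows = int(round(extent[1] / grid_size))
    if abs(n_cols * grid_size - extent[0]) > 1e-9 or abs(n_rows * grid_size - extent[1]) > 1e-9:
        raise InvalidConfigError("grid size must divide the extent")
    grid = Raster(np.zeros((n_rows, n_cols)), 0.0, 0.0, grid_size)
    if len(trees):
        agb = stem_agb_table(trees, allometry)
        row, col, inside = grid.locate(trees["x"].to_numpy(), trees["y"].to_numpy())
        np.add.at(grid.values, (row[inside], col[inside]), agb[inside])
    grid.values /= grid_size**2
    return grid


def generate_covariates(
    true_agb_250m: Raster, terrain: Raster, config: SceneConfig
) -> CovariateStack:
    """Satellite-style 250-m predictor stack coupled to true biomass.

    Vegetation indices are saturating increasing functions of true AGB with
    per-composite seeded noise (``n_composites`` pseudo-composites per
    index, mirroring a year of 16-day compositing, so q1/mean/q3 are
    non-degenerate); HV backscatter saturates in AGB with HH coupled more
    weakly; precipitation is a smooth spatial gradient; SRTM is the
    mean-aggregated terrain; X and Y are exact cell-centre coordinates.
    """
    ref = true_agb_250m
    if ref.cell_size != 250.0:
        raise CoRegistrationError(
            f"covariates are defined on a 250-m grid, got {ref.cell_size} m"
        )
    agb_mg_ha = ref.values * 10.0  # kg m^-2 -> Mg ha^-1 for the response links
    rng = _rng(config, 4)

    def composites(base: float, span: float, efold: float, noise: float) -> list[Raster]:
        out = []
        for t in range(config.n_composites):
            seasonal = 0.02 * math.sin(2.0 * math.pi * t / config.n_composites)
            vals = base + span * (1.0 - np.exp(-agb_mg_ha / efold)) + seasonal
            vals = vals + rng.normal(0.0, noise, size=vals.shape)
            out.append(ref.copy_with(np.clip(vals, -0.2, 1.0)))
        return out

    ndvi_q1, ndvi_mean, ndvi_q3 = summarize_time_series(
        composites(0.45, 0.45, 120.0, config.ndvi_noise_sd)
    )
    evi_q1, evi_mean, evi_q3 = summarize_time_series(
        composites(0.25, 0.35, 150.0, config.evi_noise_sd)
    )
    hv = ref.copy_with(
        -18.0 + 8.0 * (1.0 - np.exp(-agb_mg_ha / 130.0))
        + rng.normal(0.0, config.hv_noise_sd, size=agb_mg_ha.shape)
    )
    hh = ref.copy_with(
        -12.0 + 5.0 * (1.0 - np.exp(-agb_mg_ha / 250.0))
        + rng.normal(0.0, config.hh_noise_sd, size=agb_mg_ha.shape)
    )
    xc, yc = ref.cell_centers()
    gx, gy = np.meshgrid(xc, yc)
    trmm = ref.copy_with(
        150.0 + 100.0 * gx / max(ref.width, 1.0)
        + 30.0 * np.sin(2.0 * math.pi * gy / max(ref.height, 1.0))
    )
    srtm_fine = terrain.block_mean(250.0, min_valid_fraction=0.0)
    if srtm_fine.values.shape != ref.values.shape:
        raise PipelineError(
            "terrain does not aggregate onto the 250-m covariate grid "
            f"({srtm_fine.values.shape} vs {ref.values.shape})"
        )
    layers = {
        "ndvi_q1": ndvi_q1, "ndvi_mean": ndvi_mean, "ndvi_q3": ndvi_q3,
        "evi_q1": evi_q1, "evi_mean": evi_mean, "evi_q3": evi_q3,
        "palsar_hh": hh, "palsar_hv": hv,
        "trmm_mean": trmm,
        "srtm": ref.copy_with(srtm_fine.values),
        "x": ref.copy_with(gx),
        "y": ref.copy_with(gy),
    }
    return CovariateStack(layers)


def transect_polygon(
    center_x: float, center_y: float, azimuth: float, length: float, width: float
) -> tuple[Polygon, float]:
    """Rotated transect rectangle and its area in hectares.

    Azimuth is measured clockwise from north (degrees); the rectangle's
    long axis points along the azimuth.
    """
    if length <= 0 or width <= 0:
        raise InvalidConfigError("length and width must be positive")
    rect = box(center_x - width / 2.0, center_y - length / 2.0,
               center_x + width / 2.0, center_y + length / 2.0)
    poly = affinity.rotate(rect, -azimuth, origin=(center_x, center_y))
    return poly, length * width / 1e4


def generate_plots(
    trees: pd.DataFrame,
    config: SceneConfig,
    n_plots: int = 20,
    plot_size: float = 50.0,
) -> list[FieldPlot]:
    """Square inventory plots at seeded random positions with their stems.

    Plot corners snap to the CHM grid so plot-level TCH aggregation is
    well-defined; stems inside or on the plot boundary belong to the plot.
    """
    rng = _rng(config, 5)
    plots: list[FieldPlot] = []
    max_x = config.extent_length - plot_size
    max_y = config.extent_width - plot_size
    if max_x < 0 or max_y < 0:
        raise InvalidConfigError("plot size exceeds the scene extent")
    for i in range(n_plots):
        x0 = math.floor(rng.random() * max_x)
        y0 = math.floor(rng.random() * max_y)
        poly = box(x0, y0, x0 + plot_size, y0 + plot_size)
        if len(trees):
            sel = shapely.intersects_xy(poly, trees["x"].to_numpy(), trees["y"].to_numpy())
            stems = trees.loc[sel, ["dbh", "height", "wood_density", "growth_form"]].reset_index(drop=True)
        else:
            stems = pd.DataFrame(columns=["dbh", "height", "wood_density", "growth_form"])
        plots.append(FieldPlot(plot_id=f"plot_{i:03d}", polygon=poly, stems=stems))
    return plots


def generate_scene(
    config: SceneConfig | None = None,
    allometry: AllometryRegistry | None = None,
    simulate_cloud: bool = True,
    n_plots: int = 20,
) -> SyntheticScene:
    """Generate a full scene: terrain, stand, cloud, truth rasters, covariates.

    The 250-m products (true AGB and covariates) are built only when the
    extent is an exact multiple of 250 m in both directions; smaller test
    windows still provide terrain, stand, cloud and 50-m truth.
    """
    config = config or SceneConfig()
    config.validate()
    allometry = allometry or default_registry()
    terrain = generate_terrain(config)
    trees = generate_stand(config, terrain)
    cloud = truth = None
    if simulate_cloud:
        cloud, truth = simulate_point_cloud(terrain, trees, config)
    extent = (config.extent_length, config.extent_width)
    agb50 = true_agb_raster(trees, 50.0, allometry, extent=extent) if len(trees) else None
    agb250 = covariates = None
    if (
        agb50 is not None
        and config.extent_length % 250.0 == 0
        and config.extent_width % 250.0 == 0
        and 250.0 % config.terrain_cell_size == 0
    ):
        agb250 = agb50.block_mean(250.0, min_valid_fraction=0.0)
        covariates = generate_covariates(agb250, terrain, config)
    plots = generate_plots(trees, config, n_plots=n_plots) if len(trees) else []
    return SyntheticScene(
        config=config,
        true_dtm=terrain,
        tree_list=trees,
        cloud=cloud,
        truth=truth,
        true_agb_50m=agb50,
        true_agb_250m=agb250,
        covariates=covariates,
        plots=plots,
    )
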