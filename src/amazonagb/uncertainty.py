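"""Three-level Monte Carlo uncertainty propagation.

The biomass map's per-pixel uncertainty combines, in order:

1. the error of the inventory-plot AGB values used to calibrate the
   canopy-height power law (a relative SD applied per plot),
2. the limited sampling of calibration plots (bootstrap resampling of the
   plot set and refit of the power law per replicate), and
3. the residual variance the fitted power law cannot capture (a
   heteroscedastic residual draw per 50-m cell).

The per-cell SD across replicates forms the 50-m uncertainty raster, which
is block-averaged to 250 m (full within-block correlation assumed — canopy
structure is strongly correlated at that scale; a root-mean-variance
alternative is available).  A fourth, satellite-extrapolation stage then
redraws the 250-m training responses from truncated normal distributions,
retrains the extrapolation forest per replicate and takes the per-pixel SD
across the predicted maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import truncnorm

from .core import InvalidConfigError, PipelineError, Raster
from .wall_to_wall import (
    CovariateStack,
    RandomForestConfig,
    assemble_training,
    predict_map,
)
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "CalibrationUncertainty",
    "calibration_uncertainty_50m",
    "resample_uncertainty",
    "propagate_satellite",
]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationUncertainty:
    """Error magnitudes of the three calibration levels.

    plot_agb_relative_sd
        Level 1: relative SD of each calibration plot's AGB (dimensionless).
    n_bootstrap
        Number of Monte Carlo replicates (each replicate bootstraps the
        plot set — level 2 — on top of the level-1 perturbation).
    residual_model
        Level 3: function TCH (m) -> residual SD (kg m^-2).  Defaults to
        ``residual_relative_sd`` times the power-law prediction.
    residual_relative_sd
        Used only to build the default residual model.
    """

    plot_agb_relative_sd: float = 0.10
    n_bootstrap: int = 500
    residual_model: Callable[[np.ndarray], np.ndarray] | None = None
    residual_relative_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.plot_agb_relative_sd < 0 or self.residual_relative_sd < 0:
            raise InvalidConfigError("relative SDs must be non-negative")
        if self.n_bootstrap < 2:
            raise InvalidConfigError("n_bootstrap must be at least 2")


def _power_law(t: np.ndarray, k: float, b: float) -> np.ndarray:
    return k * np.power(t, b)


def _fit_power_law(t: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """Nonlinear least-squares fit of a = k * t**b.

    Initialized at the log-log linear solution, which is already the exact
    optimum for noiseless power-law data (so degenerate replicates refit
    identically).
    """
    slope, intercept = np.polyfit(np.log(t), np.log(a), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    popt, _ = curve_fit(_power_law, t, a, p0=p0, maxfev=2000)
    return float(popt[0]), float(popt[1])


def calibration_uncertainty_50m(
    pairs: pd.DataFrame,
    tch_50: Raster,
    cfg: CalibrationUncertainty | None = None,
    seed: int = 0,
) -> Raster:
    """Monte Carlo SD (Mg ha^-1) of the 50-m LiDAR biomass estimates.

    ``pairs`` must hold columns ``tch`` (m) and ``agb`` (kg m^-2) for the
    calibration plots.  Each replicate perturbs plot AGB (level 1),
    bootstrap-resamples the plots (level 2), refits AGB = k * TCH**b by
    nonlinear least squares, predicts every valid 50-m cell and adds a
    residual draw (level 3).  Replicates whose refit fails are discarded
    (logged); more than 20% failures is an error.
    """
    cfg = cfg or CalibrationUncertainty()
    if len(pairs) < 10:
        raise InvalidConfigError("need at least 10 calibration pairs")
    t_obs = pairs["tch"].to_numpy(dtype=float)
    a_obs = pairs["agb"].to_numpy(dtype=float)
    if np.any(t_obs <= 0):
        raise InvalidConfigError("calibration TCH values must be positive")
    residual_sd = cfg.residual_model or (
        lambda tch: cfg.residual_relative_sd * _power_law(tch, 0.05, 1.99)
    )
    rng = np.random.default_rng(seed)
    valid = tch_50.valid_mask
    tch_cells = tch_50.values[valid]
    ref_pred = None
    sums = np.zeros(tch_cells.size)
    sq_sums = np.zeros(tch_cells.size)
    n_ok = 0
    failures = 0
    sd3 = np.asarray(residual_sd(tch_cells), dtype=float)
    for _ in range(cfg.n_bootstrap):
        if cfg.plot_agb_relative_sd > 0:
            agb_r = a_obs * (1.0 + rng.normal(0.0, cfg.plot_agb_relative_sd, a_obs.size))
            agb_r = np.maximum(agb_r, 1e-9)
        else:
            agb_r = a_obs
        idx = rng.integers(0, a_obs.size, a_obs.size)
        try:
            k, b = _fit_power_law(t_obs[idx], agb_r[idx])
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        pred = _power_law(tch_cells, k, b)
        if np.any(sd3 > 0):
            pred = pred + rng.normal(0.0, 1.0, pred.size) * sd3
        # deviations from the first replicate: exact zero SD in the
        # degenerate all-noise-off case
        if ref_pred is None:
            ref_pred = pred
        dev = pred - ref_pred
        sums += dev
        sq_sums += dev**2
        n_ok += 1
    if failures:
        logger.info("calibration_uncertainty_50m: %d replicate refits failed", failures)
    if failures > 0.2 * cfg.n_bootstrap:
        raise PipelineError(
            f"{failures}/{cfg.n_bootstrap} power-law refits failed"
        )
    var = np.maximum(sq_sums / n_ok - (sums / n_ok) ** 2, 0.0)
    sd_kg_m2 = np.sqrt(var)
    out = np.full(tch_50.values.shape, np.nan)
    out[valid] = sd_kg_m2 * 10.0  # kg m^-2 -> Mg ha^-1
    return tch_50.copy_with(out)


def resample_uncertainty(
    sd_50: Raster, target_cell: float = 250.0, method: str = "mean"
) -> Raster:
    """Aggregate the 50-m SD raster to the wall-to-wall grid.

    ``mean`` (default) assumes full within-block correlation; ``rms_n``
    assumes independence: sqrt(mean variance) / sqrt(n_valid).
    """
    if method == "mean":
        return sd_50.block_mean(target_cell, min_valid_fraction=0.0)
    if method == "rms_n":
        var = sd_50.copy_with(sd_50.values**2)
        mean_var = var.block_mean(target_cell, min_valid_fraction=0.0)
        factor = int(round(target_cell / sd_50.cell_size))
        counts = sd_50.copy_with(np.isfinite(sd_50.values).astype(float)).block_mean(
            target_cell, min_valid_fraction=0.0
        )
        n_valid = counts.values * factor * factor
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.sqrt(mean_var.values) / np.sqrt(np.maximum(n_valid, 1.0))
        return mean_var.copy_with(np.where(n_valid > 0, vals, np.nan))
    raise InvalidConfigError(f"unknown SD aggregation method {method!r}")


def propagate_satellite(
    agb_250: Raster,
    sd_250: Raster,
    covariates: CovariateStack,
    model_config: RandomForestConfig | None = None,
    n_maps: int = 25,
    seed: int = 0,
    vary_model_seed: bool = True,
) -> Raster:
    """Per-pixel SD (Mg ha^-1) across replicate wall-to-wall predictions.

    For each replicate the training responses are redrawn from normal
    distributions (mean = cell AGB, SD = cell SD, truncated at zero —
    negative biomass is unphysical), the forest is retrained and the full
    map predicted; the output is the per-pixel standard deviation across
    the ``n_maps`` maps.  Replicate seeds derive from ``seed`` by a counter
    so runs parallelize reproducibly; with ``vary_model_seed=False`` the
    forest seed is held fixed and a zero SD input collapses the output SD
    to zero exactly.
    """
    model_config = model_config or RandomForestConfig()
    if n_maps < 2:
        raise InvalidConfigError("n_maps must be at least 2")
    if not agb_250.same_grid(sd_250):
        raise PipelineError("AGB and SD rasters are not co-registered")
    sd_vals = sd_250.values
    if np.any(sd_vals[np.isfinite(sd_vals)] < 0):
        raise PipelineError("negative SD encountered")
    base = assemble_training(agb_250, covariates)
    mu = base["agb"].to_numpy()
    cell_sd = sd_250.values[base["row"].to_numpy(), base["col"].to_numpy()]
    cell_sd = np.where(np.isfinite(cell_sd), cell_sd, 0.0)
    # accumulate deviations from the first replicate: numerically exact
    # zero variance when all replicates coincide
    ref_map = None
    sums = None
    sq_sums = None
    n_truncated = 0
    for r in range(n_maps):
        rep_seed = (seed * 100003 + r) % (2**31 - 1)
        rng = np.random.default_rng(rep_seed)
        y = mu.copy()
        noisy = cell_sd > 0
        if noisy.any():
            a = (0.0 - mu[noisy]) / cell_sd[noisy]
            y[noisy] = truncnorm.rvs(
                a, np.inf, loc=mu[noisy], scale=cell_sd[noisy], random_state=rng
            )
            n_truncated += int((mu[noisy] - 2 * cell_sd[noisy] < 0).sum())
        table = base.copy()
        table["agb"] = y
        model = RandomForestRegressor(
            n_estimators=model_config.n_trees,
            max_features=model_config.resolved_mtry(len(covariates.layers)),
            min_samples_leaf=model_config.min_leaf,
            random_state=rep_seed if vary_model_seed else model_config.seed,
            n_jobs=1,
        )
        X = table[[c for c in table.columns if c not in ("agb", "row", "col")]].to_numpy()
        model.fit(X, y)
        pred = predict_map(model, covariates).values
        if ref_map is None:
            ref_map = pred
            sums = np.zeros_like(pred)
            sq_sums = np.zeros_like(pred)
        dev = pred - ref_map
        sums += dev
        sq_sums += dev**2
    logger.info(
        "propagate_satellite: %d replicate draws near the zero truncation bound",
        n_truncated,
    )
    mean = sums / n_maps
    var = np.maximum(sq_sums / n_maps - mean**2, 0.0)
    return agb_250.copy_with(np.sqrt(var), origin_x=covariates.grid.origin_x,
                             origin_y=covariates.grid.origin_y)
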