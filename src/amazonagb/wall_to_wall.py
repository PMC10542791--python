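"""Wall-to-wall extrapolation of transect biomass with a random forest.

The 250-m covariate stack holds exactly the twelve predictors used for
extrapolation: quartile/mean summaries of the NDVI and EVI composite time
series, L-band radar backscatter in HH and HV, long-term mean
precipitation, elevation, and the cell-centre coordinates X and Y.  Cells
where the LiDAR transects provide an AGB estimate form the training table;
the fitted forest predicts every cell with complete covariates.

Variable importance is the total squared-error reduction attributed to
each predictor across all splits (the "relative influence" definition),
reported raw, scaled by the maximum and as a percentage of the total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import train_test_split

from .core import CoRegistrationError, InvalidConfigError, PipelineError, Raster

__all__ = [
    "PREDICTORS",
    "CovariateStack",
    "RandomForestConfig",
    "FitReport",
    "summarize_time_series",
    "resample_covariate",
    "assemble_training",
    "train_model",
    "importance_percentages",
    "predict_map",
]

logger = logging.getLogger(__name__)

PREDICTORS = (
    "ndvi_q1", "ndvi_mean", "ndvi_q3",
    "evi_q1", "evi_mean", "evi_q3",
    "palsar_hh", "palsar_hv", "trmm_mean", "srtm", "x", "y",
)


@dataclass
class CovariateStack:
    """Co-registered 250-m predictor layers, one :class:`Raster` per name."""

    layers: dict[str, Raster]

    def __post_init__(self) -> None:
        missing = [name for name in PREDICTORS if name not in self.layers]
        if missing:
            raise InvalidConfigError(f"covariate stack missing layers: {missing}")
        ref = self.layers[PREDICTORS[0]]
        for name in PREDICTORS:
            if not self.layers[name].same_grid(ref):
                raise CoRegistrationError(f"layer {name!r} is not on the stack grid")

    @property
    def grid(self) -> Raster:
        return self.layers[PREDICTORS[0]]

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def as_array(self) -> np.ndarray:
        """(n_cells, n_predictors) array in PREDICTORS order, NaN for nodata."""
        return np.column_stack([self.layers[n].values.ravel() for n in PREDICTORS])


def summarize_time_series(layers: Sequence[Raster]) -> tuple[Raster, Raster, Raster]:
    """Per-pixel first quartile, mean and third quartile of a composite series.

    Nodata composites are ignored pixel-wise; an all-nodata pixel is nodata
    in all three outputs.  Quartiles use linear interpolation between order
    statistics.
    """
    if len(layers) < 4:
        raise InvalidConfigError("need at least 4 composite layers to summarize")
    ref = layers[0]
    for lay in layers[1:]:
        if not lay.same_grid(ref):
            raise CoRegistrationError("composite layers are not co-registered")
    stack = np.stack([lay.values for lay in layers])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        q1 = np.nanpercentile(stack, 25, axis=0)
        q3 = np.nanpercentile(stack, 75, axis=0)
        mean = np.nanmean(stack, axis=0)
    return ref.copy_with(q1), ref.copy_with(mean), ref.copy_with(q3)


def resample_covariate(raster: Raster, target: Raster, method: str = "mean") -> Raster:
    """Bring a covariate onto the target grid.

    ``mean``: block average of valid source cells (target must be coarser
    by an integer factor).  ``nearest``: value of the source cell containing
    each target cell centre (any resolution relationship).
    """
    if method == "mean":
        if target.cell_size < raster.cell_size:
            raise InvalidConfigError("mean resampling cannot go to a finer grid")
        out = raster.block_mean(target.cell_size, min_valid_fraction=0.0)
        if out.values.shape != target.values.shape:
            raise CoRegistrationError("mean-resampled shape does not match target grid")
        return out.copy_with(out.values, origin_x=target.origin_x, origin_y=target.origin_y)
    if method == "nearest":
        xc, yc = target.cell_centers()
        gx, gy = np.meshgrid(xc, yc)
        row, col, inside = raster.locate(gx.ravel(), gy.ravel())
        vals = np.full(gx.size, np.nan)
        vals[inside] = raster.values[row[inside], col[inside]]
        return target.copy_with(vals.reshape(gx.shape))
    raise InvalidConfigError(f"unknown resampling method {method!r}")


def assemble_training(agb_250: Raster, covariates: CovariateStack) -> pd.DataFrame:
    """One row per cell with valid AGB response and all twelve predictors.

    Rows with any nodata predictor are dropped (count logged).  The cell
    index (row, col) is retained so predictions can be mapped back.
    """
    if not agb_250.same_grid(covariates.grid):
        raise CoRegistrationError("AGB raster and covariate stack are on different grids")
    X = covariates.as_array()
    y = agb_250.values.ravel()
    rows, cols = np.divmod(np.arange(y.size), agb_250.n_cols)
    has_response = np.isfinite(y)
    complete = np.all(np.isfinite(X), axis=1)
    keep = has_response & complete
    dropped = int(has_response.sum() - keep.sum())
    if dropped:
        logger.info("assemble_training: dropped %d cells with incomplete predictors", dropped)
    if not keep.any():
        raise PipelineError("no usable training cells (no valid AGB/predictor overlap)")
    table = pd.DataFrame(X[keep], columns=list(PREDICTORS))
    table.insert(0, "agb", y[keep])
    table["row"] = rows[keep]
    table["col"] = cols[keep]
    return table


@dataclass
class RandomForestConfig:
    """Extrapolation-model hyperparameters (fixed, seeded, configurable)."""

    n_trees: int = 500
    mtry: int | None = None        # predictors tried per split; default ceil(p / 3)
    min_leaf: int = 5
    seed: int = 0

    def resolved_mtry(self, n_predictors: int) -> int:
        return self.mtry if self.mtry is not None else int(np.ceil(n_predictors / 3))


@dataclass
class FitReport:
    """Hold-out fit quality plus the variable-importance table."""

    r2: float                      # computed on held-out rows
    rmse: float                    # Mg ha^-1
    rmse_relative: float           # fraction of the held-out mean response
    importance: pd.DataFrame       # variable, raw, scaled, percentage
    n_train: int = 0
    n_holdout: int = 0


def train_model(
    table: pd.DataFrame,
    config: RandomForestConfig | None = None,
    holdout_fraction: float = 0.2,
) -> tuple[RandomForestRegressor, FitReport]:
    """Fit the extrapolation forest and report hold-out skill and importance."""
    config = config or RandomForestConfig()
    if len(table) < 50:
        raise InvalidConfigError("training table needs at least 50 rows")
    y = table["agb"].to_numpy()
    if np.ptp(y) == 0:
        raise PipelineError("degenerate (constant) response")
    X = table[list(PREDICTORS)].to_numpy()
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=holdout_fraction, random_state=config.seed
    )
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.resolved_mtry(len(PREDICTORS)),
        min_samples_leaf=config.min_leaf,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X_tr, y_tr)
    pred = model.predict(X_ho)
    rmse = float(np.sqrt(mean_squared_error(y_ho, pred)))
    raw = model.feature_importances_
    scaled, percentage = importance_percentages(raw)
    importance = pd.DataFrame(
        {"variable": PREDICTORS, "raw": raw, "scaled": scaled, "percentage": percentage}
    ).sort_values("raw", ascending=False, ignore_index=True)
    report = FitReport(
        r2=float(r2_score(y_ho, pred)),
        rmse=rmse,
        rmse_relative=rmse / float(np.mean(y_ho)),
        importance=importance,
        n_train=len(y_tr),
        n_holdout=len(y_ho),
    )
    return model, report


def importance_percentages(raw_importance) -> tuple[np.ndarray, np.ndarray]:
    """Scale raw importances by the maximum and normalize to percentages.

    ``scaled_i = raw_i / max(raw)``, ``percentage_i = raw_i / sum(raw)``.
    """
    raw = np.asarray(raw_importance, dtype=float)
    if np.any(raw < 0):
        raise InvalidConfigError("raw importances must be non-negative")
    if raw.size == 0 or raw.max() <= 0:
        raise PipelineError("all-zero importance vector")
    return raw / raw.max(), raw / raw.sum()


def predict_map(model: RandomForestRegressor, covariates: CovariateStack) -> Raster:
    """Predict AGB (Mg ha^-1) for every cell with complete predictors.

    Cells with any nodata predictor are nodata; negative predictions are
    clamped to zero (biomass is non-negative).
    """
    if getattr(model, "n_features_in_", len(PREDICTORS)) != len(PREDICTORS):
        raise PipelineError(
            f"model expects {model.n_features_in_} predictors, stack has {len(PREDICTORS)}"
        )
    X = covariates.as_array()
    complete = np.all(np.isfinite(X), axis=1)
    out = np.full(X.shape[0], np.nan)
    if complete.any():
        out[complete] = np.maximum(model.predict(X[complete]), 0.0)
    grid = covariates.grid
    return grid.copy_with(out.reshape(grid.values.shape))
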