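"""Shared fixtures: synthetic scenes processed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from amazonagb import (
    PointCloud,
    Raster,
    SceneConfig,
    build_dtm,
    classify_ground,
    generate_scene,
    remove_outliers,
)
from amazonagb.wall_to_wall import PREDICTORS, CovariateStack


def anchored_block_keep_mask(cloud: PointCloud, voxel: float = 1.0,
                             extent: int = 4, min_neighbors: int = 5) -> np.ndarray:
    """Independent anchored-lattice neighbour counter (oracle for the filter)."""
    block = voxel * extent
    key = np.stack(
        [np.floor(cloud.x / block), np.floor(cloud.y / block), np.floor(cloud.z / block)],
        axis=1,
    ).astype(np.int64)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return counts[inv] - 1 >= min_neighbors


@pytest.fixture(scope="session")
def default_scene():
    """The default 500 m x 300 m transect scene at 4 returns per m^2."""
    return generate_scene(SceneConfig(seed=1), n_plots=40)


@pytest.fixture(scope="session")
def transect_run(default_scene):
    """Outlier filter + ground classification + DTM on the default scene,
    with truth labels carried through the filter."""
    scene = default_scene
    keep = anchored_block_keep_mask(scene.cloud)
    kept, removed = remove_outliers(scene.cloud)
    classified = classify_ground(kept)
    dtm = build_dtm(
        classified,
        origin=(0.0, 0.0),
        shape=scene.true_dtm.values.shape,
    )
    return {
        "scene": scene,
        "keep_mask": keep,
        "kept": kept,
        "removed": removed,
        "truth_kept": scene.truth[keep],
        "classified": classified,
        "dtm": dtm,
    }


@pytest.fixture(scope="session")
def regional_scene():
    """A 6.25 km x 2.5 km stand-only scene with 250 training cells."""
    cfg = SceneConfig(
        extent_length=6250.0,
        extent_width=2500.0,
        terrain_cell_size=10.0,
        density_field_cv=0.35,
        density_field_correlation=500.0,
        seed=7,
    )
    return generate_scene(cfg, simulate_cloud=False)


def make_stack(agb: Raster, seed: int = 0, noise: float = 0.0) -> CovariateStack:
    """Small deterministic covariate stack coupled linearly to an AGB raster."""
    rng = np.random.default_rng(seed)
    xc, yc = agb.cell_centers()
    gx, gy = np.meshgrid(xc, yc)
    layers = {}
    for i, name in enumerate(PREDICTORS):
        if name == "x":
            vals = gx
        elif name == "y":
            vals = gy
        else:
            vals = (i + 1) * 0.1 * agb.values + noise * rng.normal(size=agb.values.shape)
        layers[name] = agb.copy_with(np.asarray(vals, dtype=float))
    return CovariateStack(layers)
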