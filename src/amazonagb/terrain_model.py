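"""Ground classification, DTM construction and height normalization.

Ground returns are found by progressive TIN densification: the lowest
return per seed cell starts a sparse Delaunay triangulation of the terrain,
and the TIN is grown by admitting returns that lie close to the facet
beneath them both in vertical distance and in the angle subtended at the
nearest facet vertex.  After densification converges, a final labelling
pass classifies as ground every return within ``classification_distance``
of the finished TIN surface — densification builds the surface, the final
pass decides membership, which keeps noisy ground echoes near TIN vertices
from being starved out by the angle criterion.

The DTM is the linear interpolation of the ground-return TIN at 1-m cell
centres; cells outside the triangulation hull take the elevation of the
nearest ground return so the transect footprint has no holes.  Height
normalization subtracts the DTM *pixel* value (not a bilinear estimate)
from each return.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError, cKDTree

from .core import CLASS_GROUND, InvalidConfigError, PipelineError, PointCloud, Raster

__all__ = [
    "GroundFilterParams",
    "DegenerateTerrainError",
    "classify_ground",
    "build_dtm",
    "normalize_cloud",
]


class DegenerateTerrainError(PipelineError):
    """Too few or collinear seed points to triangulate a terrain surface."""


@dataclass
class GroundFilterParams:
    """Progressive-TIN densification parameters.

    seed_cell_size
        Edge of the square cells whose per-cell lowest return seeds the TIN (m).
    max_angle
        Largest angle (degrees) a candidate may subtend at the nearest facet
        vertex and still be densified into the TIN.
    max_distance
        Largest vertical distance (m) between a candidate and the facet
        beneath it for densification.
    max_iterations
        Cap on densification passes; the ground set grows weakly across
        passes so the loop always terminates.
    classification_distance
        Vertical tolerance (m) of the final labelling pass against the
        finished TIN surface.
    """

    seed_cell_size: float = 10.0
    max_angle: float = 6.0
    max_distance: float = 1.0
    max_iterations: int = 20
    classification_distance: float = 0.5

    def __post_init__(self) -> None:
        for name in ("seed_cell_size", "max_angle", "max_distance",
                     "max_iterations", "classification_distance"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")


def classify_ground(cloud: PointCloud, params: GroundFilterParams | None = None) -> PointCloud:
    """Label ground returns; outliers are assumed already removed.

    Returns a copy of the cloud with the ground set carrying LAS class 2.
    """
    params = params or GroundFilterParams()
    n = cloud.n
    if n < 3:
        raise DegenerateTerrainError("need at least 3 returns to seed a terrain TIN")
    pts = np.column_stack([cloud.x, cloud.y, cloud.z])

    ground = np.zeros(n, dtype=bool)
    ground[_seed_minima(cloud, params.seed_cell_size)] = True
    if ground.sum() < 3:
        raise DegenerateTerrainError("fewer than 3 seed minima obtained")

    tri = _triangulate(pts[ground, :2])
    tan_max = np.tan(np.radians(params.max_angle))
    for _ in range(params.max_iterations):
        cand = np.flatnonzero(~ground)
        if cand.size == 0:
            break
        dist, hdist = _tin_offsets(tri, pts[ground], pts[cand])
        ok = np.isfinite(dist) & (dist <= params.max_distance)
        # angle subtended at the nearest facet vertex (Axelsson-style)
        with np.errstate(divide="ignore", invalid="ignore"):
            ok &= dist <= tan_max * hdist
        if not ok.any():
            break
        ground[cand[ok]] = True
        tri = _triangulate(pts[ground, :2])

    # Final labelling against the finished surface; outside the TIN hull the
    # surface is extrapolated by the nearest ground return (as in the DTM).
    dist, _ = _tin_offsets(tri, pts[ground], pts)
    outside = ~np.isfinite(dist)
    if outside.any():
        tree = cKDTree(pts[ground, :2])
        _, nearest = tree.query(pts[outside, :2])
        dist[outside] = np.abs(pts[outside, 2] - pts[ground][nearest, 2])
    final = ground | (dist <= params.classification_distance)
    cls = cloud.classification.copy()
    cls[final] = CLASS_GROUND
    return PointCloud(cloud.x.copy(), cloud.y.copy(), cloud.z.copy(),
                      cloud.return_number.copy(), cls)


def _seed_minima(cloud: PointCloud, cell: float) -> np.ndarray:
    """Indices of the lowest return in each occupied seed cell."""
    cx = np.floor(cloud.x / cell).astype(np.int64)
    cy = np.floor(cloud.y / cell).astype(np.int64)
    cx -= cx.min()
    cy -= cy.min()
    key = cx * (cy.max() + 1) + cy
    order = np.lexsort((cloud.z, key))
    k_sorted = key[order]
    first = np.ones(cloud.n, dtype=bool)
    first[1:] = k_sorted[1:] != k_sorted[:-1]
    return order[first]


def _triangulate(xy: np.ndarray) -> Delaunay:
    try:
        return Delaunay(xy)
    except QhullError as exc:
        raise DegenerateTerrainError(f"degenerate triangulation: {exc}") from exc


def _tin_offsets(
    tri: Delaunay, ground_pts: np.ndarray, query_pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical distance to the facet below each query point, and the
    horizontal distance to the nearest vertex of that facet.

    Queries outside the triangulation hull get NaN distances.
    """
    q = query_pts[:, :2]
    simplex = tri.find_simplex(q)
    dist = np.full(len(q), np.nan)
    hdist = np.full(len(q), np.nan)
    inside = simplex >= 0
    if not inside.any():
        return dist, hdist
    simp = tri.simplices[simplex[inside]]           # (m, 3) vertex ids
    verts = ground_pts[simp]                        # (m, 3, 3)
    # barycentric interpolation of facet elevation at the query x, y
    T = tri.transform[simplex[inside]]              # (m, 3, 2)
    b2 = np.einsum("mij,mj->mi", T[:, :2], q[inside] - T[:, 2])
    bary = np.concatenate([b2, 1.0 - b2.sum(axis=1, keepdims=True)], axis=1)
    z_facet = np.einsum("mi,mi->m", bary, verts[:, :, 2])
    dist[inside] = np.abs(query_pts[inside, 2] - z_facet)
    d2 = np.sum((verts[:, :, :2] - q[inside, None, :]) ** 2, axis=2)
    hdist[inside] = np.sqrt(d2.min(axis=1))
    return dist, hdist


def build_dtm(ground: PointCloud, cell_size: float = 1.0,
              origin: tuple[float, float] | None = None,
              shape: tuple[int, int] | None = None,
              crs: str = "EPSG:32721") -> Raster:
    """Interpolate ground returns to a digital terrain model.

    Cell values are linear interpolation on the ground-return TIN at cell
    centres; cells outside the TIN hull are filled with the elevation of
    the nearest ground return, so the footprint carries no nodata.
    ``ground`` may be a full classified cloud (only class-2 returns are
    used) or an already ground-only cloud.
    """
    mask = ground.classification == CLASS_GROUND
    g = ground.subset(mask) if mask.any() else ground
    if g.n < 3:
        raise DegenerateTerrainError("need at least 3 ground returns for a DTM")
    if origin is None:
        origin = (np.floor(g.x.min()), np.floor(g.y.min()))
    if shape is None:
        n_cols = int(np.ceil((g.x.max() - origin[0]) / cell_size))
        n_rows = int(np.ceil((g.y.max() - origin[1]) / cell_size))
        shape = (max(n_rows, 1), max(n_cols, 1))
    xy = np.column_stack([g.x, g.y])
    try:
        interp = LinearNDInterpolator(xy, g.z)
    except QhullError as exc:
        raise DegenerateTerrainError(f"degenerate ground TIN: {exc}") from exc
    out = Raster(np.empty(shape), origin[0], origin[1], cell_size, crs)
    xc, yc = out.cell_centers()
    gx, gy = np.meshgrid(xc, yc)
    values = interp(gx, gy)
    hole = ~np.isfinite(values)
    if hole.any():
        tree = cKDTree(xy)
        _, nearest = tree.query(np.column_stack([gx[hole], gy[hole]]))
        values[hole] = g.z[nearest]
    out.values = values
    return out


def normalize_cloud(cloud: PointCloud, dtm: Raster) -> PointCloud:
    """Subtract the DTM pixel elevation from each return.

    Uses the value of the pixel containing the return (nearest-pixel, not
    bilinear).  Ground echoes may come out slightly negative.  Raises if any
    return falls outside the DTM footprint or on a nodata pixel.
    """
    row, col, inside = dtm.locate(cloud.x, cloud.y)
    if not inside.all():
        bad = np.flatnonzero(~inside)
        raise PipelineError(
            f"{bad.size} returns outside DTM footprint (first indices: {bad[:10].tolist()})"
        )
    ground_z = dtm.values[row, col]
    if not np.all(np.isfinite(ground_z)):
        bad = np.flatnonzero(~np.isfinite(ground_z))
        raise PipelineError(
            f"{bad.size} returns over nodata DTM pixels (first indices: {bad[:10].tolist()})"
        )
    return PointCloud(cloud.x.copy(), cloud.y.copy(), cloud.z - ground_z,
                      cloud.return_number.copy(), cloud.classification.copy())
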