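"""Core containers for the biomass-mapping pipeline.

Two in-memory structures are shared by every stage:

* :class:`PointCloud` — flat arrays of discrete LiDAR returns (x, y, z in
  metres, return number, classification label).
* :class:`Raster` — a regular grid with lower-left origin, square cells and
  NaN as the in-memory nodata sentinel.  The same container carries the DTM,
  CHM, TCH, AGB and SD layers at their respective resolutions.

Rasters are serialized as ESRI ASCII grids (plain text), which any GIS reads;
the CRS identifier is carried in memory and written to a ``.prj``-style
sidecar line in a companion ``.crs`` file when saving.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PipelineError",
    "InvalidConfigError",
    "FormatError",
    "CoRegistrationError",
    "CLASS_UNCLASSIFIED",
    "CLASS_GROUND",
    "CLASS_OUTLIER",
    "PointCloud",
    "Raster",
    "read_ascii_grid",
    "write_ascii_grid",
]


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class InvalidConfigError(PipelineError):
    """A configuration value violates its documented constraints."""


class FormatError(PipelineError):
    """A file on disk does not conform to the expected format."""


class CoRegistrationError(PipelineError):
    """Two grids that must share geometry do not."""


# LAS standard classification codes used throughout.
CLASS_UNCLASSIFIED = 0
CLASS_GROUND = 2
CLASS_OUTLIER = 7


@dataclass
class PointCloud:
    """Discrete LiDAR returns as parallel arrays.

    ``z`` holds elevation (m) for raw clouds and height above ground (m)
    after normalization against a DTM.  Classification uses LAS codes
    (0/1 unclassified, 2 ground, 7 outlier).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray | None = None
    classification: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).ravel()
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.z = np.asarray(self.z, dtype=np.float64).ravel()
        n = self.x.size
        if self.y.size != n or self.z.size != n:
            raise ValueError("x, y, z must have equal length")
        if self.return_number is None:
            self.return_number = np.ones(n, dtype=np.uint8)
        else:
            self.return_number = np.asarray(self.return_number, dtype=np.uint8).ravel()
        if self.classification is None:
            self.classification = np.full(n, CLASS_UNCLASSIFIED, dtype=np.uint8)
        else:
            self.classification = np.asarray(self.classification, dtype=np.uint8).ravel()
        if self.return_number.size != n or self.classification.size != n:
            raise ValueError("attribute arrays must match coordinate length")
        for arr in (self.x, self.y, self.z):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError("point coordinates must be finite")

    @property
    def n(self) -> int:
        return self.x.size

    def __len__(self) -> int:
        return self.n

    def subset(self, mask: np.ndarray) -> "PointCloud":
        """Return a new cloud holding the selected returns (boolean or index mask)."""
        return PointCloud(
            self.x[mask],
            self.y[mask],
            self.z[mask],
            self.return_number[mask],
            self.classification[mask],
        )

    def with_classification(self, classification: np.ndarray | int) -> "PointCloud":
        cls = np.broadcast_to(np.asarray(classification, dtype=np.uint8), (self.n,)).copy()
        return PointCloud(self.x.copy(), self.y.copy(), self.z.copy(),
                          self.return_number.copy(), cls)

    @staticmethod
    def concatenate(clouds: "list[PointCloud]") -> "PointCloud":
        if not clouds:
            return PointCloud(np.empty(0), np.empty(0), np.empty(0))
        return PointCloud(
            np.concatenate([c.x for c in clouds]),
            np.concatenate([c.y for c in clouds]),
            np.concatenate([c.z for c in clouds]),
            np.concatenate([c.return_number for c in clouds]),
            np.concatenate([c.classification for c in clouds]),
        )


@dataclass
class Raster:
    """Regular square-cell grid.

    ``values[row, col]`` with row 0 at the *southern* edge (y increasing with
    row index); ``origin_x/origin_y`` is the lower-left corner of the grid.
    NaN marks nodata in memory; ``nodata`` is the sentinel used on disk.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    crs: str = "EPSG:32721"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x centres of columns, y centres of rows)."""
        xc = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        yc = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xc, yc

    def locate(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map coordinates to (row, col, inside-mask).

        Points exactly on the upper/right edge are assigned to the last
        cell so a cloud spanning the full extent loses no returns.
        """
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        row = np.floor((y - self.origin_y) / self.cell_size).astype(np.int64)
        on_right = x == self.origin_x + self.width
        on_top = y == self.origin_y + self.height
        col = np.where(on_right, self.n_cols - 1, col)
        row = np.where(on_top, self.n_rows - 1, row)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        return row, col, inside

    def same_grid(self, other: "Raster", tol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    # -- data -------------------------------------------------------------
    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy_with(self, values: np.ndarray | None = None, **overrides) -> "Raster":
        """Clone grid geometry, optionally replacing the value array."""
        kwargs = dict(
            values=self.values.copy() if values is None else np.asarray(values, dtype=np.float64),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            crs=self.crs,
            nodata=self.nodata,
        )
        kwargs.update(overrides)
        return Raster(**kwargs)

    def block_mean(self, target_cell: float, min_valid_fraction: float = 0.0) -> "Raster":
        """Aggregate to a coarser grid by block mean of valid cells.

        The target cell must be an integer multiple of the source cell and
        divide the raster extent exactly.  Blocks whose valid-cell fraction
        falls below ``min_valid_fraction`` become nodata.
        """
        factor = _integer_factor(target_cell, self.cell_size)
        if self.n_rows % factor or self.n_cols % factor:
            raise CoRegistrationError(
                f"raster shape {self.values.shape} not divisible by factor {factor}"
            )
        v = self.values.reshape(self.n_rows // factor, factor, self.n_cols // factor, factor)
        valid = np.isfinite(v)
        count = valid.sum(axis=(1, 3))
        total = np.where(valid, v, 0.0).sum(axis=(1, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(count > 0, total / count, np.nan)
        frac = count / float(factor * factor)
        mean = np.where(frac >= max(min_valid_fraction, np.finfo(float).tiny), mean, np.nan)
        return Raster(mean, self.origin_x, self.origin_y, target_cell, self.crs, self.nodata)


def _integer_factor(target_cell: float, cell_size: float) -> int:
    ratio = target_cell / cell_size
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise CoRegistrationError(
            f"target cell {target_cell} is not an integer multiple of {cell_size}"
        )
    return factor


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text raster exchange format)
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (row order: north to south)."""
    path = Path(path)
    vals = np.where(raster.valid_mask, raster.values, raster.nodata)
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin_x!r}\n"
        f"yllcorner {raster.origin_y!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.6f")
    path.with_suffix(path.suffix + ".crs").write_text(raster.crs + "\n")


def read_ascii_grid(path: str | Path, crs: str | None = None) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline()
            try:
                key, val = line.split()
            except ValueError as exc:
                raise FormatError(f"malformed ASCII grid header line: {line!r}") from exc
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
        if key not in header:
            raise FormatError(f"ASCII grid header missing {key}")
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError("ASCII grid data shape does not match header")
    values = data[::-1].copy()
    values[values == header["nodata_value"]] = np.nan
    if crs is None:
        sidecar = path.with_suffix(path.suffix + ".crs")
        crs = sidecar.read_text().strip() if sidecar.exists() else "EPSG:32721"
    return Raster(values, header["xllcorner"], header["yllcorner"],
                  header["cellsize"], crs, header["nodata_value"])
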