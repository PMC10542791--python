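"""Point-cloud I/O and isolated-return filtering.

The outlier filter implements the voxel-block rule used to clean airborne
LiDAR transects before terrain modelling: space is partitioned into a fixed
lattice of 1-m voxels, each return's *block* is the 4x4x4-voxel super-voxel
(4-m cube) of that lattice containing it, and a return is isolated — hence
removed — when fewer than ``min_neighbors`` other returns fall in its block.

LAS I/O is a minimal, dependency-free reader/writer for LAS 1.2 point
formats 0–3 (the first 20 bytes of a point record are identical across
those formats).  Coordinates round-trip to the declared scale (1 cm by
default); classification maps LAS codes 2 -> ground and 7/18 -> outlier.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .core import (
    CLASS_GROUND,
    CLASS_OUTLIER,
    CLASS_UNCLASSIFIED,
    FormatError,
    InvalidConfigError,
    PointCloud,
)

__all__ = ["read_point_cloud", "write_point_cloud", "remove_outliers"]

_HEADER_FMT = "<4sHH16sBB32s32sHHHIIBHI5I12d"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)  # 227 bytes, LAS 1.2
_POINT0_SIZE = 20


def write_point_cloud(cloud: PointCloud, path: str | Path, scale: float = 0.01) -> None:
    """Write a cloud as LAS 1.2, point format 0.

    ``scale`` is the coordinate quantization step recorded in the header;
    a read-back reproduces coordinates to within ``scale / 2``.
    """
    path = Path(path)
    n = cloud.n
    if n:
        off = [float(np.floor(cloud.x.min())), float(np.floor(cloud.y.min())),
               float(np.floor(cloud.z.min()))]
        mins = [cloud.x.min(), cloud.y.min(), cloud.z.min()]
        maxs = [cloud.x.max(), cloud.y.max(), cloud.z.max()]
    else:
        off, mins, maxs = [0.0] * 3, [0.0] * 3, [0.0] * 3
    header = struct.pack(
        _HEADER_FMT,
        b"LASF", 0, 0, b"\0" * 16, 1, 2,
        b"amazonagb".ljust(32, b"\0"), b"amazonagb".ljust(32, b"\0"),
        0, 0, _HEADER_SIZE, _HEADER_SIZE, 0, 0, _POINT0_SIZE, n,
        n, 0, 0, 0, 0,
        scale, scale, scale, off[0], off[1], off[2],
        maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2],
    )
    rec = np.zeros(n, dtype=_point0_dtype())
    rec["X"] = np.round((cloud.x - off[0]) / scale).astype(np.int32)
    rec["Y"] = np.round((cloud.y - off[1]) / scale).astype(np.int32)
    rec["Z"] = np.round((cloud.z - off[2]) / scale).astype(np.int32)
    rn = np.clip(cloud.return_number, 1, 7).astype(np.uint8)
    rec["flags"] = (rn & 0x07) | ((rn & 0x07) << 3)
    rec["classification"] = cloud.classification
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())


def read_point_cloud(path: str | Path) -> PointCloud:
    """Read a LAS 1.x file (point formats 0–3) into a :class:`PointCloud`."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise FormatError(f"{path}: truncated LAS header at offset {len(raw)}")
    fields = struct.unpack(_HEADER_FMT, raw[:_HEADER_SIZE])
    if fields[0] != b"LASF":
        raise FormatError(f"{path}: bad signature at offset 0 (expected 'LASF')")
    offset_to_points = fields[11]
    point_format = fields[13]
    record_length = fields[14]
    n_points = fields[15]
    sx, sy, sz, ox, oy, oz = fields[21:27]
    if point_format > 5 or record_length < _POINT0_SIZE:
        raise FormatError(
            f"{path}: unsupported point format {point_format} "
            f"(record length {record_length}) at offset 104"
        )
    need = offset_to_points + n_points * record_length
    if len(raw) < need:
        raise FormatError(f"{path}: point data truncated at offset {len(raw)}")
    dt = _point0_dtype(record_length)
    rec = np.frombuffer(raw, dtype=dt, count=n_points, offset=offset_to_points)
    x = rec["X"] * sx + ox
    y = rec["Y"] * sy + oy
    z = rec["Z"] * sz + oz
    return_number = (rec["flags"] & 0x07).astype(np.uint8)
    las_cls = (rec["classification"] & 0x1F).astype(np.uint8)
    cls = np.full(n_points, CLASS_UNCLASSIFIED, dtype=np.uint8)
    cls[las_cls == CLASS_GROUND] = CLASS_GROUND
    cls[(las_cls == 7) | (las_cls == 18)] = CLASS_OUTLIER
    return PointCloud(x, y, z, return_number, cls)


def _point0_dtype(itemsize: int = _POINT0_SIZE) -> np.dtype:
    return np.dtype(
        {
            "names": ["X", "Y", "Z", "intensity", "flags", "classification",
                      "scan_angle", "user_data", "point_source"],
            "formats": ["<i4", "<i4", "<i4", "<u2", "u1", "u1", "i1", "u1", "<u2"],
            "offsets": [0, 4, 8, 12, 14, 15, 16, 17, 18],
            "itemsize": itemsize,
        }
    )


# ---------------------------------------------------------------------------
# Isolated-point removal
# ---------------------------------------------------------------------------

def remove_outliers(
    cloud: PointCloud,
    voxel_size: float = 1.0,
    block_extent: int = 4,
    min_neighbors: int = 5,
) -> tuple[PointCloud, PointCloud]:
    """Split a cloud into (kept, removed) by the isolated-point rule.

    A return's neighbour count is the number of *other* returns inside the
    ``block_extent``-voxel cube of the fixed lattice that contains it (blocks
    anchored at coordinates congruent to 0 modulo ``block_extent *
    voxel_size``).  Returns with fewer than ``min_neighbors`` neighbours are
    removed and labelled with the LAS outlier code; a return with exactly
    ``min_neighbors`` neighbours survives.  The result is independent of
    point order.
    """
    if voxel_size <= 0:
        raise InvalidConfigError("voxel_size must be positive")
    if block_extent < 1:
        raise InvalidConfigError("block_extent must be >= 1")
    n = cloud.n
    if n == 0:
        empty = cloud.subset(np.zeros(0, dtype=bool))
        return empty, empty
    block = voxel_size * block_extent
    key = (
        np.floor(cloud.x / block).astype(np.int64),
        np.floor(cloud.y / block).astype(np.int64),
        np.floor(cloud.z / block).astype(np.int64),
    )
    # Collapse the 3-D block index to one label per occupied block.
    order = np.lexsort(key)
    stacked = np.stack([k[order] for k in key], axis=1)
    new_block = np.ones(n, dtype=bool)
    new_block[1:] = np.any(stacked[1:] != stacked[:-1], axis=1)
    label_sorted = np.cumsum(new_block) - 1
    labels = np.empty(n, dtype=np.int64)
    labels[order] = label_sorted
    population = np.bincount(labels)
    neighbors = population[labels] - 1
    keep = neighbors >= min_neighbors
    kept = cloud.subset(keep)
    removed = cloud.subset(~keep).with_classification(CLASS_OUTLIER)
    return kept, removed
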