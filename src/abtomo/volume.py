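"""Tomographic volume container and I/O.

A reconstructed micro-CT volume is held as a 3D scalar grid of grey values
with an isotropic voxel size in micrometres.  Axis order is fixed as
(plane, row, column), plane index increasing along the rotation axis, which
matches multi-page TIFF stack order; all voxel offsets are 0-based.

The voxel size is always user-supplied metadata and never read from TIFF
resolution tags, which are unreliable for synchrotron reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "split_volume",
    "project_volume",
    "effective_voxel_size",
]

#: cubic micrometres per cubic centimetre
UM3_PER_CM3 = 1e12


@dataclass
class Volume:
    """A 3D grey-level scalar field with isotropic voxel geometry.

    Parameters
    ----------
    data
        3D array of grey values, axis order (plane, row, column).
    voxel_size
        Isotropic voxel edge length in µm; must be positive and finite.
    offset
        0-based voxel coordinates of this grid's origin within a parent
        volume (all zeros for a stand-alone volume).
    meta
        Free-form provenance (source path, bit depth, ...).
    """

    data: np.ndarray
    voxel_size: float
    offset: tuple[int, int, int] = (0, 0, 0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume data must be 3D with every extent >= 1, got shape {self.data.shape}"
            )
        if not (math.isfinite(self.voxel_size) and self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive and finite, got {self.voxel_size}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite grey values")
        self.offset = tuple(int(o) for o in self.offset)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    @property
    def physical_extent_um(self) -> tuple[float, float, float]:
        """Edge lengths of the grid in µm."""
        return tuple(n * self.voxel_size for n in self.data.shape)  # type: ignore[return-value]

    @property
    def physical_volume_cm3(self) -> float:
        """Probed tissue volume V_c in cm³ (voxel count × voxel_size³ × 1e-12)."""
        return self.n_voxels * self.voxel_size**3 / UM3_PER_CM3


def effective_voxel_size(detector_pixel_um: float, magnification: float) -> float:
    """Effective isotropic voxel size from detector pixel pitch and optics.

    A detector with pixel size ``detector_pixel_um`` coupled to magnifying
    optics of factor ``magnification`` samples the object at
    ``detector_pixel_um / magnification`` per voxel edge.
    """
    if detector_pixel_um <= 0 or magnification <= 0:
        raise ValueError("detector pixel size and magnification must be positive")
    return detector_pixel_um / magnification


def read_volume(path: str | Path, voxel_size: float) -> Volume:
    """Read a multi-page TIFF stack into a :class:`Volume`.

    Grey values are preserved bit-exactly for integer inputs and
    value-exactly for 32-bit float inputs.  ``voxel_size`` (µm) is caller
    metadata; resolution tags in the file are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    if not (math.isfinite(voxel_size) and voxel_size > 0):
        raise ValueError(f"voxel_size must be positive and finite, got {voxel_size}")
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
        data = tif.asarray()
    if data.ndim == 2:  # single-page stack
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF sample format in {path}: shape {data.shape}")
    return Volume(
        data=data,
        voxel_size=float(voxel_size),
        meta={"source": str(path), "dtype": str(data.dtype)},
    )


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as a multi-page TIFF stack.

    Round-trip contract: ``read_volume(path, v.voxel_size)`` reproduces the
    grid and shape of ``v`` exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(path, volume.data, photometric="minisblack")


def _chunk_starts(extent: int, chunk: int, step: int) -> list[int]:
    starts = list(range(0, extent - chunk + 1, step))
    if starts[-1] + chunk < extent:
        starts.append(extent - chunk)
    return starts


def split_volume(
    volume: Volume,
    chunk_extents: Sequence[int],
    overlap: int = 0,
) -> list[Volume]:
    """Split a volume into overlapping chunks for bounded-memory processing.

    Chunks are ``chunk_extents`` voxels per axis; consecutive chunks along a
    split axis share exactly ``overlap`` planes (the last chunk may be
    shifted backwards so the union of chunks covers every voxel).  Chunk
    ``offset`` fields locate each chunk in the parent grid.

    With ``overlap`` at least the extent of the largest object of interest,
    every object lies entirely inside at least one chunk, which is what the
    stitched detection pass relies on.
    """
    chunk_extents = tuple(int(c) for c in chunk_extents)
    if len(chunk_extents) != 3:
        raise ValueError("chunk_extents must give one extent per axis")
    if overlap < 0:
        raise ValueError(f"overlap must be non-negative, got {overlap}")
    for ax, (c, n) in enumerate(zip(chunk_extents, volume.shape)):
        if c < 1 or c > n:
            raise ValueError(f"chunk extent {c} invalid for axis {ax} of extent {n}")
        if c < n and overlap >= c:
            raise ValueError(f"overlap {overlap} must be smaller than chunk extent {c}")

    per_axis_starts = []
    for c, n in zip(chunk_extents, volume.shape):
        step = c - overlap if c < n else c
        per_axis_starts.append(_chunk_starts(n, c, max(step, 1)))

    chunks: list[Volume] = []
    for s0 in per_axis_starts[0]:
        for s1 in per_axis_starts[1]:
            for s2 in per_axis_starts[2]:
                sub = volume.data[
                    s0 : s0 + chunk_extents[0],
                    s1 : s1 + chunk_extents[1],
                    s2 : s2 + chunk_extents[2],
                ]
                chunks.append(
                    Volume(
                        data=sub,
                        voxel_size=volume.voxel_size,
                        offset=(
                            volume.offset[0] + s0,
                            volume.offset[1] + s1,
                            volume.offset[2] + s2,
                        ),
                        meta=dict(volume.meta, parent_shape=volume.shape, overlap=int(overlap)),
                    )
                )
    return chunks


def chunk_manifest(chunks: Sequence[Volume]) -> list[dict]:
    """JSON-ready manifest (offsets, extents, overlap) for a chunk list."""
    return [
        {
            "offset": list(c.offset),
            "extents": list(c.shape),
            "overlap": int(c.meta.get("overlap", 0)),
        }
        for c in chunks
    ]


def project_volume(
    volume: Volume,
    axis: int,
    slab: tuple[int, int] | None = None,
    mode: str = "max",
) -> np.ndarray:
    """Project a contiguous slab of planes onto a 2D image for visual QC.

    ``slab`` is a half-open plane range ``(start, stop)`` along ``axis``
    (default: the full extent).  ``mode`` is one of ``max``, ``mean``,
    ``sum``.  Counting is never performed on projections — a projection
    merges objects that overlap along the viewing axis.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    n = volume.shape[axis]
    start, stop = slab if slab is not None else (0, n)
    if not (0 <= start < stop <= n):
        raise ValueError(f"empty or out-of-bounds slab {slab} for axis extent {n}")
    sl = [slice(None)] * 3
    sl[axis] = slice(start, stop)
    block = volume.data[tuple(sl)]
    reducers = {"max": np.max, "mean": np.mean, "sum": np.sum}
    try:
        reduce = reducers[mode]
    except KeyError:
        raise ValueError(f"mode must be one of {sorted(reducers)}, got {mode!r}") from None
    return reduce(block, axis=axis)


def iter_chunk_plane_ownership(
    chunks: Sequence[Volume], parent_extent: int, axis: int = 0
) -> Iterator[tuple[Volume, float, float]]:
    """Yield (chunk, own_lo, own_hi) half-open ownership intervals in voxels.

    Ownership boundaries sit at the midpoints of consecutive chunks' overlap
    regions along ``axis``, partitioning the parent extent so that every
    object centroid is owned by exactly one chunk.
    """
    ordered = sorted(chunks, key=lambda c: c.offset[axis])
    bounds = [0.0]
    for prev, nxt in zip(ordered, ordered[1:]):
        prev_end = prev.offset[axis] + prev.shape[axis]
        bounds.append((nxt.offset[axis] + prev_end) / 2.0)
    bounds.append(float(parent_extent))
    for chunk, lo, hi in zip(ordered, bounds, bounds[1:]):
        yield chunk, lo, hi
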