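"""Voxel representation of bundles: density maps and binary masks.

A density map counts, per voxel, the number of *distinct* streamlines of a
selection that touch the voxel — a streamline contributes at most 1 to a
voxel no matter how many of its points or segments fall inside.  A binary
mask is the support of a density map (counts > 0).

Two notions of "touches" are provided:

``points``
    the streamline has a sampled point inside the voxel cube.  Cheap, but
    misses voxels crossed between consecutive points of sparsely-sampled
    (compressed) streamlines.
``segments`` (default)
    the streamline polyline intersects the voxel cube, computed by exact
    incremental grid traversal (Amanatides–Woo 3-D DDA) of every segment.

Points outside the grid are clipped silently; a counter of fully
out-of-grid streamlines is logged as a warning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from numba import njit

from .errors import FormatError, GridMismatchError
from .grid import ReferenceGrid
from .tract_io import Selection, Tractogram

__all__ = [
    "DensityMap", "BinaryMask",
    "density_map", "binary_mask", "selection_mask",
    "write_map", "read_density_map", "read_mask",
]

logger = logging.getLogger(__name__)


@dataclass
class DensityMap:
    """Per-voxel count of distinct streamlines intersecting the voxel."""

    grid: ReferenceGrid
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise ValueError(
                f"counts shape {self.counts.shape} != grid shape {self.grid.shape}")
        if np.issubdtype(self.counts.dtype, np.floating):
            self.counts = self.counts.astype(np.int32)
        if self.counts.min(initial=0) < 0:
            raise ValueError("density counts must be non-negative")

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass
class BinaryMask:
    """Boolean per-voxel support of a bundle."""

    grid: ReferenceGrid
    support: np.ndarray

    def __post_init__(self):
        self.support = np.asarray(self.support).astype(bool)
        if self.support.shape != self.grid.shape:
            raise ValueError(
                f"support shape {self.support.shape} != grid shape {self.grid.shape}")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.support))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume


@njit(cache=True)
def _traverse_polyline(pts):  # pragma: no cover - exercised via density_map
    """Voxels crossed by a polyline, in shifted voxel coordinates where voxel
    (i,j,k) spans [i,i+1)x[j,j+1)x[k,k+1).  Returns (m,3) int64 with
    possible duplicates; may include out-of-grid voxels."""
    n = pts.shape[0]
    cap = 4 * (n + 2)
    out = np.empty((cap, 3), np.int64)
    m = 0
    for s in range(n - 1):
        px, py, pz = pts[s, 0], pts[s, 1], pts[s, 2]
        qx, qy, qz = pts[s + 1, 0], pts[s + 1, 1], pts[s + 1, 2]
        ix, iy, iz = np.int64(np.floor(px)), np.int64(np.floor(py)), np.int64(np.floor(pz))
        jx, jy, jz = np.int64(np.floor(qx)), np.int64(np.floor(qy)), np.int64(np.floor(qz))
        dx, dy, dz = qx - px, qy - py, qz - pz
        sx = 1 if dx > 0 else -1
        sy = 1 if dy > 0 else -1
        sz = 1 if dz > 0 else -1
        big = 1.0e30
        if dx != 0.0:
            tx = ((ix + (1 if sx > 0 else 0)) - px) / dx
            dtx = sx / dx
        else:
            tx, dtx = big, big
        if dy != 0.0:
            ty = ((iy + (1 if sy > 0 else 0)) - py) / dy
            dty = sy / dy
        else:
            ty, dty = big, big
        if dz != 0.0:
            tz = ((iz + (1 if sz > 0 else 0)) - pz) / dz
            dtz = sz / dz
        else:
            tz, dtz = big, big
        nsteps = abs(jx - ix) + abs(jy - iy) + abs(jz - iz)
        needed = m + nsteps + 1
        if needed > out.shape[0]:
            new = np.empty((2 * needed, 3), np.int64)
            new[:m] = out[:m]
            out = new
        out[m, 0], out[m, 1], out[m, 2] = ix, iy, iz
        m += 1
        for _ in range(nsteps):
            if tx <= ty and tx <= tz:
                ix += sx
                tx += dtx
            elif ty <= tz:
                iy += sy
                ty += dty
            else:
                iz += sz
                tz += dtz
            out[m, 0], out[m, 1], out[m, 2] = ix, iy, iz
            m += 1
    return out[:m]


def _streamline_voxels(pts_world: np.ndarray, grid: ReferenceGrid,
                       mode: str) -> np.ndarray:
    """Unique in-grid flat voxel ids touched by one streamline."""
    shifted = grid.world_to_voxel(pts_world) + 0.5
    if mode == "points":
        vox = np.floor(shifted).astype(np.int64)
    elif mode == "segments":
        vox = _traverse_polyline(np.ascontiguousarray(shifted))
    else:
        raise ValueError(f"mode must be 'points' or 'segments', got {mode!r}")
    shape = np.asarray(grid.shape)
    ok = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[ok]
    if vox.size == 0:
        return np.empty(0, np.int64)
    flat = (vox[:, 0] * shape[1] + vox[:, 1]) * shape[2] + vox[:, 2]
    return np.unique(flat)


def density_map(parent: Tractogram, sel: Selection | None = None,
                mode: str = "segments") -> DensityMap:
    """Count, per voxel, how many distinct selected streamlines touch it."""
    if sel is None:
        sel = parent.all_indices()
    sel.validate_against(parent)
    counts = np.zeros(parent.grid.shape, dtype=np.int32)
    flat_counts = counts.reshape(-1)
    n_outside = 0
    for i in sel.indices:
        flat = _streamline_voxels(parent.streamlines[i], parent.grid, mode)
        if flat.size == 0:
            n_outside += 1
            continue
        flat_counts[flat] += 1
    if n_outside:
        logger.warning("%d streamline(s) entirely outside the grid contributed "
                       "nothing to the density map", n_outside)
    return DensityMap(parent.grid, counts)


def binary_mask(d: DensityMap) -> BinaryMask:
    return BinaryMask(d.grid, d.counts > 0)


def selection_mask(parent: Tractogram, sel: Selection,
                   mode: str = "segments") -> BinaryMask:
    """Shortcut: binary support of a selection."""
    return binary_mask(density_map(parent, sel, mode=mode))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_map(m: DensityMap | BinaryMask, path) -> None:
    """Save as NIfTI-1: int32 counts for densities, uint8 for masks."""
    if isinstance(m, DensityMap):
        data = m.counts.astype(np.int32)
    elif isinstance(m, BinaryMask):
        data = m.support.astype(np.uint8)
    else:
        raise TypeError(f"expected DensityMap or BinaryMask, got {type(m)}")
    nib.Nifti1Image(data, m.grid.affine).to_filename(str(path))


def _load_img(path, grid: ReferenceGrid | None):
    try:
        img = nib.load(str(path))
    except Exception as e:
        raise FormatError(f"cannot read {path}: {e}") from e
    file_grid = ReferenceGrid.from_nifti(img)
    if grid is not None:
        grid.require_compatible(file_grid, atol=1e-5)
    return np.asanyarray(img.dataobj), file_grid


def read_density_map(path, grid: ReferenceGrid | None = None) -> DensityMap:
    data, g = _load_img(path, grid)
    return DensityMap(g, np.asarray(data).astype(np.int32))


def read_mask(path, grid: ReferenceGrid | None = None) -> BinaryMask:
    data, g = _load_img(path, grid)
    return BinaryMask(g, np.asarray(data) > 0)
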