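"""Reference voxel grid shared by all representations.

A :class:`ReferenceGrid` is the (shape, affine) pair of a NIfTI header: a
3-D array of voxels together with the 4x4 transform mapping 0-based voxel
indices to world coordinates in millimetres (RAS+ orientation).  Voxel
centers sit at integer voxel coordinates; voxel ``i`` spans the half-open
cube ``[i - 0.5, i + 0.5)`` along each axis ("corner" convention), so a
world point belongs to the voxel ``floor(inv(affine) @ point + 0.5)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import GridMismatchError

__all__ = ["ReferenceGrid"]


@dataclass
class ReferenceGrid:
    """Voxel grid: 3-D shape plus voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) <= 0.0:
            raise ValueError("affine is singular: voxel volume would be zero")
        self._inv_affine = np.linalg.inv(self.affine)

    # -- constructors ------------------------------------------------------

    @classmethod
    def isotropic(cls, shape=(32, 32, 32), spacing: float = 1.0,
                  origin=(0.0, 0.0, 0.0)) -> "ReferenceGrid":
        """Axis-aligned grid with equal voxel spacing (mm)."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = float(spacing)
        aff[:3, 3] = origin
        return cls(tuple(shape), aff)

    @classmethod
    def from_nifti(cls, source) -> "ReferenceGrid":
        """Grid from a NIfTI file path or a loaded nibabel image."""
        img = source if hasattr(source, "affine") else nib.load(str(source))
        return cls(tuple(img.shape[:3]), np.asarray(img.affine))

    # -- geometry ----------------------------------------------------------

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates (centers at integers) of world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        vox = np.atleast_2d(np.asarray(voxels, dtype=np.float64))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_indices(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel index of each world point (corner convention)."""
        return np.floor(self.world_to_voxel(points) + 0.5).astype(np.int64)

    def in_bounds(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(indices)
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)

    # -- comparison --------------------------------------------------------

    def is_compatible(self, other: "ReferenceGrid", atol: float = 1e-3) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.affine, other.affine, atol=atol))

    def require_compatible(self, other: "ReferenceGrid", atol: float = 1e-3):
        if not self.is_compatible(other, atol=atol):
            raise GridMismatchError(
                f"grids differ: shape {self.shape} vs {other.shape} or affines "
                f"beyond {atol} tolerance")
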