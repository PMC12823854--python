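"""Shared voxel-grid geometry.

Every stage of the pipeline operates on volumes that live on a common
:class:`VolumeGrid`: a 3-D array shape plus a 4x4 affine mapping 0-based
voxel indices to RAS world coordinates in millimetres.  The default
analysis grid is isotropic 3 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid"]


def _round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (deterministic)."""
    values = np.asarray(values, dtype=float)
    return np.trunc(values + np.copysign(0.5, values))


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid with its voxel->mm affine.

    Parameters
    ----------
    shape
        Number of voxels along each axis (three positive integers).
    affine
        4x4 matrix mapping 0-based voxel indices to RAS mm coordinates.
    """

    shape: tuple
    affine: np.ndarray = field(repr=False)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, shape=(24, 24, 24), voxel_size_mm: float = 3.0,
                  centered: bool = True) -> "VolumeGrid":
        """Axis-aligned isotropic grid; if *centered*, mm origin sits at
        the grid centre (between voxels for even shapes)."""
        shape = tuple(int(s) for s in shape)
        affine = np.eye(4)
        affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size_mm
        if centered:
            affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size_mm
        return cls(shape=shape, affine=affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_mm(self, ijk) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel_continuous(self, xyz) -> np.ndarray:
        """Inverse-affine image of mm coordinates (no rounding)."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return (xyz - self.affine[:3, 3]) @ inv[:3, :3].T

    def mm_to_voxel(self, xyz) -> np.ndarray:
        """Nearest voxel index for mm coordinates.

        Rounds half away from zero on each axis so that tie-breaking is
        deterministic; the result may lie outside the grid (see
        :meth:`contains`).
        """
        return _round_half_away(self.mm_to_voxel_continuous(xyz)).astype(int)

    def contains(self, ijk) -> np.ndarray:
        """Elementwise test that voxel indices fall inside the grid."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=int))
        ok = np.all((ijk >= 0) & (ijk < np.asarray(self.shape)), axis=1)
        return ok if ok.size > 1 else bool(ok[0])

    def mm_coordinates(self) -> np.ndarray:
        """World mm coordinates of every voxel centre, shape (*shape, 3)."""
        idx = np.indices(self.shape, dtype=float)  # (3, X, Y, Z)
        ijk = np.moveaxis(idx, 0, -1)
        return self.voxel_to_mm(ijk)

    def matches(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)
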