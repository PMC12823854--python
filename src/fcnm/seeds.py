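"""Contrast seed construction.

Each source study (contrast) reports a handful of peak coordinates;
these are converted to MNI space where needed, a small sphere (default
4 mm radius) is drawn around every coordinate, and the spheres are
unioned into one binary *contrast seed* restricted to a brain/GM mask.
Contrasts whose seed ends up empty after masking are excluded, mirroring
the rule that drops studies whose coordinates all fall outside gray
matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid
from .io import CoordinateTable

logger = logging.getLogger(__name__)

__all__ = [
    "LANCASTER_ICBM_SPM_TO_TAL",
    "talairach_to_mni",
    "mni_to_talairach",
    "table_to_mni",
    "sphere_mask",
    "ContrastSeed",
    "build_contrast_seeds",
]

# Lancaster et al. (2007) best-fit affine taking SPM/ICBM MNI coordinates
# to Talairach space ("icbm_spm2tal").  Talairach -> MNI uses its inverse.
LANCASTER_ICBM_SPM_TO_TAL = np.array([
    [0.9254, 0.0024, -0.0118, -1.0207],
    [-0.0048, 0.9316, -0.0871, -1.7667],
    [0.0152, 0.0883, 0.8924, 4.0926],
    [0.0, 0.0, 0.0, 1.0],
])

_TAL_TO_MNI = np.linalg.inv(LANCASTER_ICBM_SPM_TO_TAL)


def _apply_affine(matrix: np.ndarray, xyz) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ matrix[:3, :3].T + matrix[:3, 3]


def talairach_to_mni(xyz, transform: np.ndarray | None = None) -> np.ndarray:
    """Convert Talairach mm coordinates to MNI space.

    ``transform`` may override the shipped Lancaster matrix and is the
    *forward* MNI->Talairach affine; its inverse is applied here.
    """
    mni2tal = LANCASTER_ICBM_SPM_TO_TAL if transform is None else np.asarray(transform)
    return _apply_affine(np.linalg.inv(mni2tal), xyz)


def mni_to_talairach(xyz, transform: np.ndarray | None = None) -> np.ndarray:
    """Forward MNI -> Talairach conversion (used when synthesising tables)."""
    mni2tal = LANCASTER_ICBM_SPM_TO_TAL if transform is None else np.asarray(transform)
    return _apply_affine(mni2tal, xyz)


def table_to_mni(table: CoordinateTable, transform: np.ndarray | None = None) -> CoordinateTable:
    """Return a copy of *table* with every row expressed in MNI space.

    MNI-tagged rows pass through unchanged; Talairach rows are converted.
    """
    df = table.data.copy()
    tal = df["space"] == "Talairach"
    if tal.any():
        converted = talairach_to_mni(df.loc[tal, ["x", "y", "z"]].to_numpy(), transform)
        df.loc[tal, ["x", "y", "z"]] = converted
        df.loc[tal, "space"] = "MNI"
    return CoordinateTable(df)


def sphere_mask(grid: VolumeGrid, center_mm, radius_mm: float) -> np.ndarray:
    """Binary mask of voxels whose centres lie within *radius_mm* (mm,
    Euclidean, boundary included) of *center_mm*.

    Drawn in world space, so a 1-mm radius on a 3-mm grid legitimately
    yields at most the single nearest voxel.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center_mm, dtype=float)
    mask = np.zeros(grid.shape, dtype=bool)
    # candidate bounding box: inverse-affine image of the mm cube around center
    corners = center + radius_mm * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float)
    idx = grid.mm_to_voxel_continuous(corners)
    lo = np.maximum(np.floor(idx.min(axis=0)).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(idx.max(axis=0)).astype(int) + 2, grid.shape)
    if np.any(lo >= hi):
        return mask
    ranges = [np.arange(lo[a], hi[a]) for a in range(3)]
    box = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1)
    mm = grid.voxel_to_mm(box)
    inside = np.linalg.norm(mm - center, axis=-1) <= radius_mm
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside
    return mask


@dataclass
class ContrastSeed:
    """Union-of-spheres seed mask for one contrast."""

    study_id: str
    contrast_id: str
    mask: np.ndarray
    n_coordinates: int
    radius_mm: float
    n_dropped_spheres: int = 0

    @property
    def key(self):
        return (self.study_id, self.contrast_id)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def build_contrast_seeds(table: CoordinateTable, grid: VolumeGrid,
                         radius_mm: float = 4.0,
                         brain_mask: np.ndarray | None = None,
                         transform: np.ndarray | None = None):
    """Build one :class:`ContrastSeed` per unique (study, contrast).

    Coordinates are first converted to MNI, a sphere is drawn around
    each, spheres are unioned and intersected with ``brain_mask``.
    Contrasts left with an empty seed are excluded (returned in the
    second element with a reason), mirroring the rule that drops studies
    whose coordinates fall entirely outside the gray-matter mask.

    Returns
    -------
    (seeds, excluded)
        ``seeds`` is a list of :class:`ContrastSeed`; ``excluded`` a list
        of ``{"study_id", "contrast_id", "reason"}`` dicts.
    """
    if len(table) == 0:
        raise ValueError("empty coordinate table")
    if brain_mask is None:
        brain_mask = np.ones(grid.shape, dtype=bool)
    brain_mask = np.asarray(brain_mask).astype(bool)
    table = table_to_mni(table, transform)

    seeds, excluded = [], []
    for study_id, contrast_id in table.contrast_keys():
        rows = table.coordinates_for(study_id, contrast_id)
        union = np.zeros(grid.shape, dtype=bool)
        dropped = 0
        for xyz in rows[["x", "y", "z"]].to_numpy():
            sph = sphere_mask(grid, xyz, radius_mm)
            if not sph.any():
                dropped += 1
                logger.warning("contrast %s/%s: sphere at %s has no in-grid voxel",
                               study_id, contrast_id, np.round(xyz, 1))
                continue
            union |= sph
        union &= brain_mask
        if not union.any():
            reason = "all spheres outside grid" if dropped == len(rows) else \
                "seed empty after brain-mask intersection"
            excluded.append({"study_id": study_id, "contrast_id": contrast_id,
                             "reason": reason})
            logger.warning("contrast %s/%s excluded: %s", study_id, contrast_id, reason)
            continue
        seeds.append(ContrastSeed(study_id=study_id, contrast_id=contrast_id,
                                  mask=union, n_coordinates=len(rows),
                                  radius_mm=float(radius_mm),
                                  n_dropped_spheres=dropped))
    if not seeds:
        raise ValueError("all contrasts excluded: no usable seed masks")
    return seeds, excluded
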