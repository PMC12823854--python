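"""Seed-to-whole-brain functional connectivity maps.

For each contrast seed and subject: the seed time series is the
unweighted mean over seed voxels, each in-mask voxel's Pearson
correlation with that series is computed, and the map is Fisher
z-transformed (atanh of r clipped to |r| <= 1 - 1e-7 so that
self-correlated seed voxels stay finite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid
from .preprocess import PreprocessedScan
from .seeds import ContrastSeed

logger = logging.getLogger(__name__)

__all__ = ["FCMap", "seed_timeseries", "fc_map"]

R_CLIP = 1.0 - 1e-7


@dataclass
class FCMap:
    """Fisher-z seed-connectivity map for one subject x contrast."""

    z: np.ndarray
    contrast_id: str
    subject_id: str
    grid: VolumeGrid

    @property
    def key(self):
        return (self.subject_id, self.contrast_id)


def seed_timeseries(prep: PreprocessedScan, seed: ContrastSeed) -> np.ndarray:
    """Unweighted mean time series over usable seed voxels."""
    mask = seed.mask & prep.usable_mask
    if not mask.any():
        raise ValueError(
            f"seed {seed.study_id}/{seed.contrast_id} has no usable voxel")
    return prep.bold[mask].mean(axis=0)


def fc_map(prep: PreprocessedScan, seed: ContrastSeed,
           min_timepoints: int = 10) -> FCMap:
    """Voxelwise Pearson r against the seed series, Fisher z-transformed.

    Voxels outside ``usable_mask`` (or with zero variance) are NaN; the
    number of zero-variance in-mask voxels is logged.
    """
    if prep.n_timepoints < min_timepoints:
        raise ValueError(f"need >= {min_timepoints} usable volumes, "
                         f"got {prep.n_timepoints}")
    ts = seed_timeseries(prep, seed)
    ts_c = ts - ts.mean()
    ts_norm = np.linalg.norm(ts_c)
    if ts_norm == 0:
        raise ValueError(f"seed {seed.study_id}/{seed.contrast_id} "
                         "has a constant time series")
    data = prep.bold[prep.usable_mask]  # (V, T)
    centred = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    zero_var = norms == 0
    if zero_var.any():
        logger.info("subject %s contrast %s: %d zero-variance voxels -> NaN",
                    prep.subject_id, seed.contrast_id, int(zero_var.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centred @ ts_c / (norms * ts_norm)
    r[zero_var] = np.nan
    z_vals = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z = np.full(prep.grid.shape, np.nan)
    z[prep.usable_mask] = z_vals
    return FCMap(z=z, contrast_id=seed.contrast_id,
                 subject_id=prep.subject_id, grid=prep.grid)
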