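"""Group-level network mapping.

The core of the method: per contrast, a voxelwise one-sample t-test over
subjects' Fisher-z maps; one-sided (right-tail) p-values because only
positive connectivity is carried forward; voxel-level Benjamini-Hochberg
FDR thresholding and binarisation; then the binary maps of all contrasts
are summed into an overlap probability map and thresholded at >= 50% of
contrasts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grid import VolumeGrid
from .fc import FCMap

logger = logging.getLogger(__name__)

__all__ = ["GroupTMap", "BinarizedNetworkMap", "OverlapProbabilityMap",
           "one_sample_t", "fdr_threshold", "overlap_map"]


@dataclass
class GroupTMap:
    """Voxelwise one-sample t statistics with one-sided p-values."""

    t: np.ndarray
    df: int
    p_onesided: np.ndarray
    contrast_id: str
    grid: VolumeGrid


@dataclass
class BinarizedNetworkMap:
    """FDR-thresholded, binarised positive-FC map for one contrast."""

    mask: np.ndarray
    q_level: float
    n_suprathreshold: int
    contrast_id: str
    grid: VolumeGrid


@dataclass
class OverlapProbabilityMap:
    """Voxelwise count of contrasts whose thresholded map covers the
    voxel, with the >= ceil(fraction * n) final mask."""

    counts: np.ndarray
    n_contrasts: int
    threshold_fraction: float
    final_mask: np.ndarray
    grid: VolumeGrid

    @property
    def min_count(self) -> int:
        return required_count(self.threshold_fraction, self.n_contrasts)


def required_count(fraction: float, n: int) -> int:
    # 1e-9 guards against float noise in fraction * n (e.g. 0.1 * 30)
    return int(math.ceil(fraction * n - 1e-9))


def one_sample_t(z_maps, contrast_id: str | None = None) -> GroupTMap:
    """Voxelwise one-sample t-test across subjects.

    ``t = mean / (sd / sqrt(n))`` over subjects with finite values;
    one-sided right-tail p from Student's t with df = n_valid - 1.
    Voxels with fewer than 3 valid subjects are NaN.  Zero-sd voxels
    take t = +/-inf (p = 0 or 1); all-zero voxels take t = 0, p = 0.5.
    """
    arrays = [m.z if isinstance(m, FCMap) else np.asarray(m, float) for m in z_maps]
    if len(arrays) < 3:
        raise ValueError("need at least 3 subjects")
    grid = None
    for m in z_maps:
        if isinstance(m, FCMap):
            if grid is not None and not grid.matches(m.grid):
                raise ValueError("inconsistent grids across subjects")
            grid = m.grid
            if contrast_id is None:
                contrast_id = m.contrast_id
    if grid is None:
        grid = VolumeGrid.isotropic(arrays[0].shape, 1.0, centered=False)
    stack = np.stack(arrays)
    if any(a.shape != stack.shape[1:] for a in arrays):
        raise ValueError("inconsistent shapes across subjects")
    valid = np.isfinite(stack)
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(valid, stack, 0.0), axis=0) / np.maximum(n, 1), np.nan)
        sq = np.nansum(np.where(valid, (stack - mean) ** 2, 0.0), axis=0)
        sd = np.sqrt(sq / np.maximum(n - 1, 1))
        t = mean / (sd / np.sqrt(n))
    # degenerate sd == 0: +/-inf for nonzero mean, 0 for all-zero voxels
    degen = (sd == 0) & (n >= 3)
    t[degen & (mean > 0)] = np.inf
    t[degen & (mean < 0)] = -np.inf
    t[degen & (mean == 0)] = 0.0
    t[n < 3] = np.nan
    df = n - 1
    with np.errstate(invalid="ignore"):
        p = np.where(np.isfinite(t) & (n >= 3),
                     stats.t.sf(np.nan_to_num(t), df=np.maximum(df, 1)), np.nan)
    p[t == np.inf] = 0.0
    p[t == -np.inf] = 1.0
    nominal_df = len(arrays) - 1
    return GroupTMap(t=t, df=nominal_df, p_onesided=p,
                     contrast_id=contrast_id or "", grid=grid)


def fdr_threshold(tmap: GroupTMap, q: float = 0.05,
                  mask: np.ndarray | None = None) -> BinarizedNetworkMap:
    """Benjamini-Hochberg over the one-sided p of all in-mask voxels;
    survivors with t > 0 form the binary map.

    An empty result is valid (the contrast still counts toward the
    overlap denominator); a warning is logged.
    """
    if mask is None:
        mask = np.ones(tmap.t.shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("analysis mask is empty")
    pool = mask & np.isfinite(tmap.p_onesided)
    out = np.zeros(tmap.t.shape, dtype=bool)
    p = tmap.p_onesided[pool]
    if p.size:
        reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
        out[pool] = reject & (tmap.t[pool] > 0)
    n_sup = int(out.sum())
    if n_sup == 0:
        logger.warning("contrast %s: no suprathreshold voxels at q=%.3g",
                       tmap.contrast_id, q)
    return BinarizedNetworkMap(mask=out, q_level=q, n_suprathreshold=n_sup,
                               contrast_id=tmap.contrast_id, grid=tmap.grid)


def overlap_map(binmaps, threshold_fraction: float = 0.5) -> OverlapProbabilityMap:
    """Sum binary contrast maps voxelwise and threshold at
    >= ceil(threshold_fraction * n_contrasts) ("at least 50%" rule)."""
    binmaps = list(binmaps)
    if not binmaps:
        raise ValueError("need at least one binarized map")
    grid = binmaps[0].grid
    for b in binmaps[1:]:
        if not grid.matches(b.grid):
            raise ValueError("grid mismatch across binarized maps")
    counts = np.sum([b.mask.astype(np.int32) for b in binmaps], axis=0)
    n = len(binmaps)
    final = counts >= required_count(threshold_fraction, n)
    return OverlapProbabilityMap(counts=counts, n_contrasts=n,
                                 threshold_fraction=float(threshold_fraction),
                                 final_mask=final, grid=grid)
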