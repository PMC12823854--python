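"""Chemoarchitecture: spatial correlation with neurotransmitter maps.

JuSpace-style analysis: the binary network map and each PET-derived
annotation map are aggregated to a gray-matter parcellation, the
parcel vectors are correlated (Spearman by default; tracer units are
used only ordinally), significance comes from an exchangeable
parcel-label permutation null (two-sided, add-one corrected), and the
resulting p-values are Benjamini-Hochberg adjusted across the map set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import LabelAtlas

logger = logging.getLogger(__name__)

__all__ = ["AnnotationMap", "parcellate", "spatial_correlation", "correlate_all"]

MIN_PARCELS = 10


@dataclass
class AnnotationMap:
    """A named voxelwise molecular annotation (e.g. receptor density)."""

    name: str
    values: np.ndarray


def parcellate(volume: np.ndarray, scheme: LabelAtlas) -> np.ndarray:
    """Per-parcel mean of finite in-parcel values -> vector of length P.

    Binary maps yield the parcel coverage fraction.  Parcels with no
    finite value are NaN (warned) and are dropped pairwise downstream.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != scheme.labels.shape:
        raise ValueError("volume and parcellation are on different grids")
    labels = scheme.label_ids
    if len(labels) < MIN_PARCELS:
        warnings.warn(f"only {len(labels)} parcels; permutation inference "
                      f"is unreliable below {MIN_PARCELS}")
    out = np.full(len(labels), np.nan)
    finite = np.isfinite(volume)
    for i, label in enumerate(labels):
        sel = (scheme.labels == label) & finite
        if sel.any():
            out[i] = volume[sel].mean()
        else:
            warnings.warn(f"parcel {label} has no finite value; NaN")
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(xc @ yc / denom)


def spatial_correlation(network_vec: np.ndarray, annot_vec: np.ndarray,
                        n_perm: int = 5000,
                        rng: np.random.Generator | int | None = None,
                        method: str = "spearman", null: str = "exchangeable"):
    """Correlation between two parcel vectors with a permutation p-value.

    The default null randomly permutes the annotation vector's parcel
    assignment ``n_perm`` times;
    ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)`` (two-sided).
    ``null="rotation"`` instead applies random cyclic shifts along the
    parcel order, which preserves the neighbourhood (autocorrelation)
    structure of an ordered parcellation; it is a conservative option
    when annotation maps are spatially smooth.

    Returns ``(r, p_perm)``.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(network_vec, dtype=float)
    y = np.asarray(annot_vec, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("parcel vectors must be 1-D and equal length")
    pair = np.isfinite(x) & np.isfinite(y)
    x, y = x[pair], y[pair]
    if x.size < MIN_PARCELS:
        raise ValueError(f"need >= {MIN_PARCELS} paired finite parcels, got {x.size}")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method '{method}'")
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("constant vector: correlation undefined")
    r_obs = float(xc @ yc / (nx * ny))
    base = np.arange(x.size)
    if null == "exchangeable":
        # permutation of parcel labels == permutation of one (ranked) vector
        idx = np.argsort(rng.random((n_perm, x.size)), axis=1)
    elif null == "rotation":
        shifts = rng.integers(1, x.size, size=n_perm)
        idx = (base[None, :] + shifts[:, None]) % x.size
    else:
        raise ValueError(f"unknown null model '{null}'")
    r_perm = (yc[idx] @ xc) / (nx * ny)
    p = (1.0 + np.sum(np.abs(r_perm) >= np.abs(r_obs) - 1e-12)) / (n_perm + 1.0)
    return r_obs, float(p)


def correlate_all(network_vec: np.ndarray, annotations, scheme: LabelAtlas | None = None,
                  n_perm: int = 5000, seed: int | None = 0,
                  method: str = "spearman", alpha: float = 0.05,
                  null: str = "exchangeable") -> pd.DataFrame:
    """Correlate the network parcel vector against every annotation map,
    then BH-FDR adjust across maps.

    ``annotations`` may be :class:`AnnotationMap` volumes (``scheme``
    required to parcellate them) or ready ``(name, vector)`` pairs.
    Deterministic given *seed*.  Returns a DataFrame with columns
    name, r, p_perm, p_fdr, significant.
    """
    pairs = []
    for ann in annotations:
        if isinstance(ann, AnnotationMap):
            if scheme is None:
                raise ValueError("parcellation scheme required for volume annotations")
            pairs.append((ann.name, parcellate(ann.values, scheme)))
        else:
            name, vec = ann
            pairs.append((str(name), np.asarray(vec, dtype=float)))
    if not pairs:
        raise ValueError("need at least one annotation map")
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate annotation map name(s): {dup}")
    rng = np.random.default_rng(seed)
    rows = []
    for name, vec in pairs:
        r, p = spatial_correlation(network_vec, vec, n_perm=n_perm, rng=rng,
                                   method=method, null=null)
        rows.append({"name": name, "r": r, "p_perm": p})
    df = pd.DataFrame(rows)
    _, p_fdr, *_ = multipletests(df["p_perm"], alpha=alpha, method="fdr_bh")
    df["p_fdr"] = p_fdr
    df["significant"] = df["p_fdr"] < alpha
    return df
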