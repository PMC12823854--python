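"""Reading and writing the standard on-disk formats.

NIfTI-1 is the sole volume format (gzip transparently supported through
nibabel).  Coordinate tables are CSV/TSV with a header; motion parameters
are whitespace-delimited T x 6 text (3 translations in mm, 3 rotations in
radians); label atlases are integer NIfTI volumes plus a JSON name map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VolumeGrid

__all__ = [
    "CoordinateTable",
    "CoordinateTableError",
    "LabelAtlas",
    "SubjectScan",
    "load_volume",
    "save_volume",
    "load_label_atlas",
    "save_label_atlas",
    "read_coordinate_table",
    "read_motion_params",
]

#: Default header aliases for coordinate tables (lower-cased match).
COLUMN_ALIASES = {
    "study_id": ("study_id", "study", "paper", "publication"),
    "contrast_id": ("contrast_id", "contrast", "experiment"),
    "x": ("x",),
    "y": ("y",),
    "z": ("z",),
    "space": ("space", "coordinate_space", "coord_space", "reference"),
}

#: Recognised coordinate-space labels (upper-cased match).
SPACE_ALIASES = {
    "MNI": "MNI",
    "MNI152": "MNI",
    "ICBM": "MNI",
    "TAL": "Talairach",
    "TALAIRACH": "Talairach",
}


class CoordinateTableError(ValueError):
    """Malformed coordinate table (missing column, bad value...)."""


@dataclass
class CoordinateTable:
    """Peak-coordinate table: one row per reported coordinate.

    ``data`` holds the normalised columns ``study_id, contrast_id, x, y,
    z, space`` in file order; ``space`` is ``"MNI"`` or ``"Talairach"``.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = ["study_id", "contrast_id", "x", "y", "z", "space"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise CoordinateTableError(f"missing column(s): {', '.join(missing)}")
        df = self.data.loc[:, required].reset_index(drop=True)
        if len(df) == 0:
            raise CoordinateTableError("coordinate table is empty")
        xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(xyz).all():
            bad = np.where(~np.isfinite(xyz).all(axis=1))[0]
            raise CoordinateTableError(f"non-finite coordinates in row(s) {list(bad)}")
        if (df["contrast_id"].astype(str).str.len() == 0).any():
            raise CoordinateTableError("empty contrast_id")
        bad_space = set(df["space"]) - {"MNI", "Talairach"}
        if bad_space:
            raise CoordinateTableError(f"unknown coordinate space label(s): {bad_space}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def contrast_keys(self) -> list:
        """Unique (study_id, contrast_id) pairs in first-appearance order."""
        seen, keys = set(), []
        for s, c in zip(self.data["study_id"], self.data["contrast_id"]):
            if (s, c) not in seen:
                seen.add((s, c))
                keys.append((s, c))
        return keys

    def coordinates_for(self, study_id, contrast_id) -> pd.DataFrame:
        df = self.data
        return df[(df["study_id"] == study_id) & (df["contrast_id"] == contrast_id)]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_coordinate_table(path, aliases=None) -> CoordinateTable:
    """Read and validate a coordinate CSV/TSV.

    Raises
    ------
    CoordinateTableError
        If a required column is missing (named in the message) or a
        coordinate cannot be parsed (the data line number is named).
    """
    path = Path(path)
    aliases = {**COLUMN_ALIASES, **(aliases or {})}
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str,
                      skipinitialspace=True)
    lower = {c.lower().strip(): c for c in raw.columns}
    resolved = {}
    for target, names in aliases.items():
        for name in names:
            if name.lower() in lower:
                resolved[target] = lower[name.lower()]
                break
        else:
            raise CoordinateTableError(
                f"{path.name}: missing required column '{target}' "
                f"(accepted aliases: {', '.join(names)})")
    df = pd.DataFrame({t: raw[c] for t, c in resolved.items()})
    for axis in ("x", "y", "z"):
        parsed = pd.to_numeric(df[axis], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            # +2: one for the header line, one for 0- vs 1-based counting
            lines = [int(i) + 2 for i in np.where(bad)[0]]
            raise CoordinateTableError(
                f"{path.name}: unparseable {axis} value on line(s) {lines}")
        df[axis] = parsed.astype(float)
    spaces = df["space"].astype(str).str.strip().str.upper()
    unknown = sorted(set(spaces) - set(SPACE_ALIASES))
    if unknown:
        raise CoordinateTableError(f"{path.name}: unknown space label(s) {unknown}")
    df["space"] = [SPACE_ALIASES[s] for s in spaces]
    df["study_id"] = df["study_id"].astype(str).str.strip()
    df["contrast_id"] = df["contrast_id"].astype(str).str.strip()
    return CoordinateTable(df)


# ---------------------------------------------------------------------------
# volumes


def _grid_from_img(img) -> VolumeGrid:
    return VolumeGrid(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))


def load_volume(path):
    """Load a NIfTI volume -> (data array, VolumeGrid)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), _grid_from_img(img)


def save_volume(path, data, grid: VolumeGrid) -> None:
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation on a grid; label 0 is background."""

    labels: np.ndarray
    names: dict
    grid: VolumeGrid

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != tuple(self.grid.shape):
            raise ValueError("atlas labels do not match grid shape")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = set(np.unique(self.labels)) - {0}
        unnamed = sorted(int(l) for l in present if int(l) not in self.names)
        if unnamed:
            raise ValueError(f"atlas labels without names: {unnamed}")

    @property
    def label_ids(self) -> list:
        return sorted(self.names)

    def mask_for(self, label: int) -> np.ndarray:
        return self.labels == label


def load_label_atlas(nii_path, names_json) -> LabelAtlas:
    labels, grid = load_volume(nii_path)
    with open(names_json) as fh:
        names = json.load(fh)
    return LabelAtlas(labels=np.rint(labels).astype(int), names=names, grid=grid)


def save_label_atlas(atlas: LabelAtlas, nii_path, names_json) -> None:
    save_volume(nii_path, atlas.labels.astype(np.int16), atlas.grid)
    with open(names_json, "w") as fh:
        json.dump({str(k): v for k, v in atlas.names.items()}, fh, indent=1)


def read_motion_params(path) -> np.ndarray:
    """Whitespace-delimited T x 6 motion text file -> (T, 6) array."""
    motion = np.loadtxt(str(path), dtype=float)
    motion = np.atleast_2d(motion)
    if motion.shape[1] != 6:
        raise ValueError(f"motion file must have 6 columns, got {motion.shape[1]}")
    return motion


# ---------------------------------------------------------------------------
# subject scans


@dataclass
class SubjectScan:
    """One subject's 4-D resting-state acquisition plus masks and motion.

    ``bold`` is (X, Y, Z, T) in arbitrary signal units; ``motion`` is
    (T, 6) with translations in mm and rotations in radians; ``tr`` in
    seconds.  All masks share the bold grid.
    """

    subject_id: str
    bold: np.ndarray
    motion: np.ndarray
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    tr: float
    grid: VolumeGrid

    def __post_init__(self):
        self.bold = np.asarray(self.bold, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        if self.bold.ndim != 4:
            raise ValueError("bold must be 4-D (X, Y, Z, T)")
        if self.bold.shape[:3] != tuple(self.grid.shape):
            raise ValueError("bold does not match grid shape")
        if self.motion.shape != (self.bold.shape[3], 6):
            raise ValueError("motion must be (T, 6) matching bold length")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        for name in ("brain_mask", "gm_mask", "wm_mask", "csf_mask"):
            mask = np.asarray(getattr(self, name)).astype(bool)
            if mask.shape != tuple(self.grid.shape):
                raise ValueError(f"{name} does not match grid shape")
            setattr(self, name, mask)

    @property
    def n_timepoints(self) -> int:
        return self.bold.shape[3]
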