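"""Confound removal for already-aligned 4-D resting-state data.

The chain mirrors a standard DPABI-style stream on data that are assumed
to sit on a common grid already: drop initial volumes, compute framewise
displacement (Power's formula, 50-mm rotation radius), apply head-motion
exclusion (2 mm / 2 degrees), regress nuisance covariates (linear drift,
Friston-24 motion expansion, FD > 0.5 mm spike indicators, global/WM/CSF
mean signals), ideal-FFT bandpass 0.01-0.1 Hz, and Gaussian smoothing
(6 mm FWHM).  Regression precedes filtering; both are single-pass OLS /
rectangular-FFT operations, so the whole chain is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace, field

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid
from .io import SubjectScan

logger = logging.getLogger(__name__)

__all__ = [
    "NuisanceDesign",
    "PreprocessedScan",
    "drop_initial_volumes",
    "framewise_displacement",
    "motion_exclusion",
    "friston24",
    "build_nuisance_design",
    "residualize",
    "bandpass",
    "regress_and_filter",
    "smooth",
    "preprocess_scan",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Arc radius (mm) converting rotations to displacements in Power's FD.
FD_ROTATION_RADIUS_MM = 50.0


def drop_initial_volumes(scan: SubjectScan, n_drop: int = 10) -> SubjectScan:
    """Discard the first *n_drop* volumes (signal-equilibration period)."""
    if scan.n_timepoints <= n_drop:
        raise ValueError(
            f"scan has {scan.n_timepoints} volumes, cannot drop {n_drop}")
    if n_drop == 0:
        return scan
    return replace(scan, bold=scan.bold[..., n_drop:], motion=scan.motion[n_drop:])


def framewise_displacement(motion: np.ndarray,
                           rotation_radius_mm: float = FD_ROTATION_RADIUS_MM) -> np.ndarray:
    """Power's framewise displacement in mm.

    Sum of absolute backward differences of the six motion parameters,
    with rotations (radians) converted to arc length on a sphere of
    ``rotation_radius_mm``.  The first element is 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (T, 6)")
    if not np.isfinite(motion).all():
        raise ValueError("non-finite motion parameters")
    diff = np.diff(motion, axis=0)
    diff[:, 3:] *= rotation_radius_mm
    fd = np.zeros(len(motion))
    fd[1:] = np.abs(diff).sum(axis=1)
    return fd


def motion_exclusion(scan: SubjectScan, max_translation_mm: float = 2.0,
                     max_rotation_deg: float = 2.0):
    """Head-motion screening: exclude if any |translation| or |rotation|
    *exceeds* the limits (equality keeps the subject).

    Returns ``(keep, qc)`` where qc records the maxima and the decision.
    """
    trans = np.abs(scan.motion[:, :3]).max() if len(scan.motion) else 0.0
    rot_deg = np.degrees(np.abs(scan.motion[:, 3:])).max() if len(scan.motion) else 0.0
    keep = not (trans > max_translation_mm or rot_deg > max_rotation_deg)
    qc = {"max_translation_mm": float(trans),
          "max_rotation_deg": float(rot_deg),
          "kept": bool(keep)}
    if not keep:
        logger.info("subject %s excluded for motion: %.2f mm / %.2f deg",
                    scan.subject_id, trans, rot_deg)
    return keep, qc


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston 24-parameter motion expansion.

    Current parameters, one-volume-lagged parameters (zeros at t=0), and
    the squares of both: (T, 24).
    """
    motion = np.asarray(motion, dtype=float)
    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, lagged, motion ** 2, lagged ** 2])


@dataclass
class NuisanceDesign:
    """Nuisance regressor matrix (T x K) with column names."""

    matrix: np.ndarray
    column_names: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("column_names must match matrix columns")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def build_nuisance_design(scan: SubjectScan, fd: np.ndarray | None = None,
                          spike_threshold_mm: float = 0.5,
                          global_signal: bool = True) -> NuisanceDesign:
    """Assemble the nuisance design for one (already truncated) scan.

    Columns: linear drift (1), Friston-24 motion expansion (24), one
    one-hot spike indicator per volume with FD strictly > 0.5 mm, and
    global / white-matter / CSF mean time series.  Global signal can be
    toggled; it is on by default.
    """
    T = scan.n_timepoints
    if fd is None:
        fd = framewise_displacement(scan.motion)
    cols, names = [], []
    cols.append(np.linspace(-0.5, 0.5, T))
    names.append("linear_drift")
    f24 = friston24(scan.motion)
    cols.extend(f24.T)
    names.extend([f"motion_{i:02d}" for i in range(24)])
    spikes = np.where(fd > spike_threshold_mm)[0]
    for t in spikes:
        onehot = np.zeros(T)
        onehot[t] = 1.0
        cols.append(onehot)
        names.append(f"spike_{int(t):03d}")
    flat = scan.bold.reshape(-1, T)
    tissue = [("wm_signal", scan.wm_mask), ("csf_signal", scan.csf_mask)]
    if global_signal:
        tissue.insert(0, ("global_signal", scan.brain_mask))
    for name, mask in tissue:
        if not mask.any():
            raise ValueError(f"empty tissue mask for {name}")
        cols.append(flat[mask.ravel()].mean(axis=0))
        names.append(name)
    return NuisanceDesign(matrix=np.column_stack(cols), column_names=names)


def _prune_collinear(X: np.ndarray, names: list, tol: float = 1e-10):
    """Drop columns that are (numerically) linear combinations of earlier
    ones, so OLS stays full rank; warns with the dropped names."""
    keep, basis = [], []
    for j in range(X.shape[1]):
        candidate = np.column_stack(basis + [X[:, j]]) if basis else X[:, j:j + 1]
        if np.linalg.matrix_rank(candidate, tol=tol * max(1.0, np.abs(X).max())) == candidate.shape[1]:
            keep.append(j)
            basis.append(X[:, j])
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear nuisance column(s): {dropped}")
    return X[:, keep]


def residualize(data: np.ndarray, design: NuisanceDesign | np.ndarray) -> np.ndarray:
    """Per-voxel OLS residuals of *data* (T x V) against the design
    (an intercept is always added)."""
    X = design.matrix if isinstance(design, NuisanceDesign) else np.asarray(design, float)
    names = (design.column_names if isinstance(design, NuisanceDesign)
             else [f"c{i}" for i in range(X.shape[1])])
    T = data.shape[0]
    if X.size and X.shape[0] != T:
        raise ValueError("design rows do not match data length")
    full = np.column_stack([np.ones(T)] + ([X] if X.size else []))
    full = _prune_collinear(full, ["intercept"] + list(names))
    beta, *_ = np.linalg.lstsq(full, data, rcond=None)
    return data - full @ beta


def bandpass(data: np.ndarray, tr: float, low_hz: float = 0.01,
             high_hz: float = 0.1) -> np.ndarray:
    """Ideal rectangular FFT bandpass along the last axis, retaining
    frequencies in [low_hz, high_hz] inclusive."""
    T = data.shape[-1]
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum = np.fft.rfft(data, axis=-1)
    spectrum[..., ~keep] = 0.0
    return np.fft.irfft(spectrum, n=T, axis=-1)


def smooth(bold: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Separable Gaussian smoothing with the stated FWHM in mm.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, converted to voxel
    units; ``fwhm_mm = 0`` is the identity.  Works on 3-D volumes or 4-D
    series (time axis last, unsmoothed).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return bold.copy()
    voxel_size = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size
    sigma = tuple(sigma_vox) + ((0.0,) if bold.ndim == 4 else ())
    return ndimage.gaussian_filter(bold, sigma=sigma)


@dataclass
class PreprocessedScan:
    """Residualised, bandpass-filtered, smoothed 4-D data plus QC."""

    subject_id: str
    bold: np.ndarray
    usable_mask: np.ndarray
    fd: np.ndarray
    qc: dict
    tr: float
    grid: VolumeGrid

    @property
    def n_timepoints(self) -> int:
        return self.bold.shape[3]


def regress_and_filter(scan: SubjectScan, design: NuisanceDesign,
                       band=(0.01, 0.1)) -> np.ndarray:
    """OLS nuisance residualisation followed by the ideal bandpass;
    returns the filtered 4-D array (unsmoothed)."""
    T = scan.n_timepoints
    flat = scan.bold.reshape(-1, T).T  # (T, V)
    resid = residualize(flat, design)
    filtered = bandpass(resid.T, scan.tr, *band)
    return filtered.reshape(scan.bold.shape)


def preprocess_scan(scan: SubjectScan, n_drop: int = 10,
                    spike_threshold_mm: float = 0.5,
                    band=(0.01, 0.1), fwhm_mm: float = 6.0,
                    global_signal: bool = True) -> PreprocessedScan:
    """Run the full confound-removal chain on one subject."""
    scan = drop_initial_volumes(scan, n_drop)
    fd = framewise_displacement(scan.motion)
    _, motion_qc = motion_exclusion(scan)
    design = build_nuisance_design(scan, fd=fd,
                                   spike_threshold_mm=spike_threshold_mm,
                                   global_signal=global_signal)
    bold = regress_and_filter(scan, design, band=band)
    bold = smooth(bold, fwhm_mm, scan.grid.voxel_size)
    variance = bold.var(axis=3)
    usable = scan.brain_mask & (variance > 0)
    qc = dict(motion_qc)
    qc["n_spikes"] = int((fd > spike_threshold_mm).sum())
    qc["n_usable_voxels"] = int(usable.sum())
    return PreprocessedScan(subject_id=scan.subject_id, bold=bold,
                            usable_mask=usable, fd=fd, qc=qc,
                            tr=scan.tr, grid=scan.grid)
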