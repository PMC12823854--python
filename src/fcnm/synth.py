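"""Synthetic connectome generator with known ground truth.

Emulates, at desk scale, the inputs the pipeline consumes: per-subject
4-D resting-state volumes on a 3-mm grid with planted spatially coherent
networks, motion traces with occasional high-FD spikes, tissue masks, a
coordinate table whose contrasts target the planted networks, a toy
8-label canonical atlas, a gray-matter parcellation, and a set of 30
annotation maps with controlled parcel-level coupling to the planted
network.

Geometry
--------
The "brain" is a 33-mm sphere centred in a 24^3 grid of 3-mm voxels;
CSF occupies r <= 4 mm, white matter 4-8 mm, gray matter the 8-33 mm
shell.  Planted network nodes are 11-mm spheres centred at cube-vertex
directions 20 mm from the origin, so each node sits inside exactly one
octant of the gray-matter shell; the canonical toy atlas labels those
octants (seven cortical-network names plus a subcortical label).
Network A has three nodes (in the octants named DefaultMode,
Frontoparietal, VentralAttention), network B two.

Signal model
------------
Every voxel carries white Gaussian noise; each planted network adds a
shared subject-specific latent time series, band-limited to the
0.01-0.1 Hz analysis passband, scaled by ``amplitude``.  Motion is a
Gaussian random walk; spike events add a one-volume 0.6-mm translation
impulse (FD > 0.5 mm at two frames) and a coincident global intensity
offset in the bold data.  Identical configs (including seed) produce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import VolumeGrid
from .io import CoordinateTable, LabelAtlas, SubjectScan
from .seeds import mni_to_talairach
from .chem import AnnotationMap

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset",
           "generate_scan", "generate_coordinates", "generate_annotations",
           "ANNOTATION_NAMES"]

#: 30 annotation-map names (receptors/transporters, JuSpace-style set).
ANNOTATION_NAMES = [
    "5HT1A", "5HT1B", "5HT2A", "5HT4", "5HT6", "SERT", "CB1", "D1", "D2",
    "DAT", "FDOPA", "GABAa", "KappaOp", "MU", "NAT", "NMDA", "VAChT",
    "mGluR5", "H3", "M1", "A4B2", "5HT2A_altanserin", "D2_raclopride",
    "SERT_madam", "GABAa_fmz", "CB1_fmpep", "DAT_fpcit", "MU_carfentanil",
    "NAT_mrb", "FDOPA_alt",
]

_BRAIN_RADIUS = 33.0
_CSF_RADIUS = 4.0
_WM_RADIUS = 8.0
_NODE_RADIUS = 11.0
_NODE_DISTANCE = 20.0

# Octant (sign of x, y, z) -> canonical network name.  Network A's nodes
# occupy the three (+x) octants listed first; B's the two (-x, -y) ones.
_OCTANT_NAMES = {
    (1, 1, 1): "DefaultMode",
    (1, 1, -1): "Frontoparietal",
    (1, -1, 1): "VentralAttention",
    (1, -1, -1): "Limbic",
    (-1, 1, 1): "DorsalAttention",
    (-1, 1, -1): "Somatomotor",
    (-1, -1, 1): "Visual",
    (-1, -1, -1): "Subcortical",
}
#: Yeo-style label order (1..7 cortical + 8 subcortical).
CANONICAL_ORDER = ["Visual", "Somatomotor", "DorsalAttention",
                   "VentralAttention", "Limbic", "Frontoparietal",
                   "DefaultMode", "Subcortical"]

_NETWORK_A_SIGNS = [(1, 1, 1), (1, 1, -1), (1, -1, 1)]
_NETWORK_B_SIGNS = [(-1, -1, -1), (-1, -1, 1)]


def _default_couplings() -> dict:
    return {"5HT2A": 0.6, "CB1": 0.6, "mGluR5": 0.6}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the real analysis at desk scale: 3-mm grid, HCP-like
    TR of 0.72 s, 210 volumes before the 10-volume drop, 10 contrasts.
    ``amplitude`` is the planted latent's scale relative to unit noise;
    the default 0.06 puts post-smoothing seed-network correlations in
    the weak-but-detectable regime (see docs/methods.md).
    """

    shape: tuple = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_subjects: int = 20
    n_timepoints: int = 210
    tr: float = 0.72
    amplitude: float = 0.06
    noise_sd: float = 1.0
    motion_walk_sd_mm: float = 0.01
    motion_walk_sd_rad: float = 0.0002
    spike_prob: float = 0.02
    spike_translation_mm: float = 0.6
    spike_bold_offset: float = 2.0
    n_contrasts: int = 10
    coords_per_contrast: int = 3
    coordinate_jitter_mm: float = 1.5
    talairach_fraction: float = 0.2
    scenario: str = "single"          # "single" | "split"
    n_annotations: int = 30
    coupled_annotations: dict = field(default_factory=_default_couplings)
    n_parcels: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in ("single", "split"):
            raise ValueError(f"unknown scenario '{self.scenario}'")
        for name, rho in self.coupled_annotations.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"coupling for {name} must be in [0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class SyntheticDataset:
    """Everything the pipeline needs, plus the ground truth."""

    config: SyntheticConfig
    grid: VolumeGrid
    scans: list
    coordinates: CoordinateTable
    atlas: LabelAtlas
    parcels: LabelAtlas
    annotations: list
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    network_masks: dict          # name -> bool array ("A", "B")
    network_parcel_vec: np.ndarray  # standardized parcel coverage of network A
    contrast_targets: dict       # (study_id, contrast_id) -> network name


# ---------------------------------------------------------------------------
# geometry


def make_grid(cfg: SyntheticConfig) -> VolumeGrid:
    return VolumeGrid.isotropic(cfg.shape, cfg.voxel_size_mm, centered=True)


def _radii(grid: VolumeGrid) -> np.ndarray:
    return np.linalg.norm(grid.mm_coordinates(), axis=-1)


def make_tissue_masks(grid: VolumeGrid):
    """Spherical brain with concentric CSF / WM cores and a GM shell."""
    r = _radii(grid)
    brain = r <= _BRAIN_RADIUS
    csf = r <= _CSF_RADIUS
    wm = (r > _CSF_RADIUS) & (r <= _WM_RADIUS)
    gm = brain & ~csf & ~wm
    return brain, gm, wm, csf


def _node_center(signs) -> np.ndarray:
    return np.asarray(signs, dtype=float) * _NODE_DISTANCE / np.sqrt(3.0)


def make_network_masks(grid: VolumeGrid) -> dict:
    """Planted networks: disjoint unions of 11-mm spherical nodes."""
    mm = grid.mm_coordinates()
    masks = {}
    for name, sign_list in (("A", _NETWORK_A_SIGNS), ("B", _NETWORK_B_SIGNS)):
        mask = np.zeros(grid.shape, dtype=bool)
        for signs in sign_list:
            center = _node_center(signs)
            mask |= np.linalg.norm(mm - center, axis=-1) <= _NODE_RADIUS
        masks[name] = mask
    return masks


def make_canonical_atlas(grid: VolumeGrid, gm_mask: np.ndarray) -> LabelAtlas:
    """Toy 8-network atlas: octants of the gray-matter shell."""
    mm = grid.mm_coordinates()
    name_to_label = {n: i + 1 for i, n in enumerate(CANONICAL_ORDER)}
    labels = np.zeros(grid.shape, dtype=np.int16)
    signs = np.where(mm >= 0, 1, -1)
    for sign_tuple, name in _OCTANT_NAMES.items():
        sel = np.all(signs == np.asarray(sign_tuple), axis=-1) & gm_mask
        labels[sel] = name_to_label[name]
    names = {v: k for k, v in name_to_label.items()}
    return LabelAtlas(labels=labels, names=names, grid=grid)


def make_parcellation(grid: VolumeGrid, gm_mask: np.ndarray,
                      n_parcels: int = 100) -> LabelAtlas:
    """Deterministic gray-matter parcellation: raster-order chunks of
    near-equal size (a toy stand-in for an anatomical parcellation)."""
    flat_idx = np.flatnonzero(gm_mask.ravel())
    chunks = np.array_split(flat_idx, n_parcels)
    labels = np.zeros(grid.n_voxels, dtype=np.int16)
    for i, chunk in enumerate(chunks):
        labels[chunk] = i + 1
    names = {i + 1: f"parcel_{i + 1:03d}" for i in range(n_parcels)}
    return LabelAtlas(labels=labels.reshape(grid.shape), names=names, grid=grid)


# ---------------------------------------------------------------------------
# scans


def _band_limited_series(rng: np.random.Generator, T: int, tr: float,
                         low: float = 0.01, high: float = 0.1) -> np.ndarray:
    """Unit-sd time series with power restricted to [low, high] Hz."""
    white = rng.standard_normal(T)
    freqs = np.fft.rfftfreq(T, d=tr)
    spectrum = np.fft.rfft(white)
    spectrum[(freqs < low) | (freqs > high)] = 0.0
    series = np.fft.irfft(spectrum, n=T)
    sd = series.std()
    return series / sd if sd > 0 else series


def generate_scan(cfg: SyntheticConfig, subject_index: int,
                  grid: VolumeGrid | None = None,
                  masks=None, network_masks: dict | None = None) -> SubjectScan:
    """One subject's 4-D scan with planted network signal and motion.

    Deterministic in (cfg.seed, subject_index); shared geometry objects
    may be passed in to avoid recomputation.
    """
    grid = grid or make_grid(cfg)
    if masks is None:
        masks = make_tissue_masks(grid)
    brain, gm, wm, csf = masks
    network_masks = network_masks or make_network_masks(grid)
    rng = np.random.default_rng([cfg.seed, int(subject_index)])
    T = cfg.n_timepoints

    bold = rng.normal(0.0, cfg.noise_sd, size=grid.shape + (T,))
    for name in sorted(network_masks):
        latent = _band_limited_series(rng, T, cfg.tr)
        bold[network_masks[name]] += cfg.amplitude * latent

    motion = np.cumsum(
        rng.normal(0.0, 1.0, size=(T, 6))
        * np.array([cfg.motion_walk_sd_mm] * 3 + [cfg.motion_walk_sd_rad] * 3),
        axis=0)
    spikes = np.flatnonzero(rng.random(T) < cfg.spike_prob)
    for t in spikes:
        motion[t, 0] += cfg.spike_translation_mm          # one-volume impulse
        bold[brain, t] += cfg.spike_bold_offset * cfg.noise_sd

    return SubjectScan(subject_id=f"sub-{subject_index:03d}", bold=bold,
                       motion=motion, brain_mask=brain, gm_mask=gm,
                       wm_mask=wm, csf_mask=csf, tr=cfg.tr, grid=grid)


# ---------------------------------------------------------------------------
# coordinates


def _sample_coordinate(rng, grid, mask, jitter_mm: float) -> np.ndarray:
    """Random voxel centre within *mask*, jittered by <= 1 voxel."""
    candidates = np.argwhere(mask)
    ijk = candidates[rng.integers(len(candidates))]
    mm = grid.voxel_to_mm(ijk)
    return mm + rng.uniform(-jitter_mm, jitter_mm, size=3)


def generate_coordinates(cfg: SyntheticConfig, grid: VolumeGrid | None = None,
                         network_masks: dict | None = None,
                         gm_mask: np.ndarray | None = None):
    """Coordinate table targeting the planted networks.

    ``scenario="single"``: every contrast draws one coordinate per
    network-A node (recovery conditions).  ``scenario="split"``: 40% of
    contrasts target A, 40% B, 20% scattered gray matter away from both
    (specificity conditions).  A configurable fraction of rows is
    emitted in Talairach space to exercise the conversion.

    Returns ``(CoordinateTable, targets)`` with the per-contrast target
    network name ("A", "B" or "background").
    """
    grid = grid or make_grid(cfg)
    if gm_mask is None:
        _, gm_mask, _, _ = make_tissue_masks(grid)
    network_masks = network_masks or make_network_masks(grid)
    rng = np.random.default_rng([cfg.seed, 10_001])
    mm = grid.mm_coordinates()

    node_masks_a = [
        (np.linalg.norm(mm - _node_center(s), axis=-1) <= _NODE_RADIUS)
        for s in _NETWORK_A_SIGNS]
    node_masks_b = [
        (np.linalg.norm(mm - _node_center(s), axis=-1) <= _NODE_RADIUS)
        for s in _NETWORK_B_SIGNS]
    # background pool: GM at least ~2 voxels away from any planted node
    near = np.zeros(grid.shape, dtype=bool)
    for s in _NETWORK_A_SIGNS + _NETWORK_B_SIGNS:
        near |= np.linalg.norm(mm - _node_center(s), axis=-1) <= _NODE_RADIUS + 6.0
    background = gm_mask & ~near

    if cfg.scenario == "single":
        targets = ["A"] * cfg.n_contrasts
    else:
        n_a = int(round(0.4 * cfg.n_contrasts))
        n_b = int(round(0.4 * cfg.n_contrasts))
        targets = ["A"] * n_a + ["B"] * n_b + \
            ["background"] * (cfg.n_contrasts - n_a - n_b)

    rows = []
    target_map = {}
    for i, target in enumerate(targets):
        study_id, contrast_id = f"study{i + 1:02d}", "c1"
        target_map[(study_id, contrast_id)] = target
        pools = {"A": node_masks_a, "B": node_masks_b,
                 "background": [background]}[target]
        for j in range(cfg.coords_per_contrast):
            pool = pools[j % len(pools)]
            xyz = _sample_coordinate(rng, grid, pool, cfg.coordinate_jitter_mm)
            space = "MNI"
            if rng.random() < cfg.talairach_fraction:
                xyz = mni_to_talairach(xyz)
                space = "Talairach"
            rows.append({"study_id": study_id, "contrast_id": contrast_id,
                         "x": xyz[0], "y": xyz[1], "z": xyz[2], "space": space})
    return CoordinateTable(pd.DataFrame(rows)), target_map


# ---------------------------------------------------------------------------
# annotations


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def network_parcel_vector(network_mask: np.ndarray, parcels: LabelAtlas) -> np.ndarray:
    """Standardized per-parcel coverage fraction of the planted network."""
    labels = parcels.label_ids
    cov = np.empty(len(labels))
    for i, label in enumerate(labels):
        sel = parcels.labels == label
        cov[i] = network_mask[sel].mean()
    return _standardize(cov)


def generate_annotations(cfg: SyntheticConfig, network_vec: np.ndarray,
                         parcels: LabelAtlas,
                         rng: np.random.Generator | None = None) -> list:
    """Annotation maps with controlled parcel-level coupling.

    Each map is built at parcel level as
    ``rho * standardized(network_vec) + sqrt(1 - rho^2) * noise`` and
    broadcast to voxels (NaN outside the parcellation); ``rho`` is 0
    unless the map name appears in ``cfg.coupled_annotations``.
    """
    rng = rng or np.random.default_rng([cfg.seed, 20_002])
    names = ANNOTATION_NAMES[:cfg.n_annotations]
    if cfg.n_annotations > len(ANNOTATION_NAMES):
        names = names + [f"annot_{i}" for i in range(len(ANNOTATION_NAMES),
                                                     cfg.n_annotations)]
    z = _standardize(np.asarray(network_vec, dtype=float))
    maps = []
    label_arr = parcels.labels
    for name in names:
        rho = float(cfg.coupled_annotations.get(name, 0.0))
        noise = _standardize(rng.standard_normal(z.size))
        vec = rho * z + np.sqrt(1.0 - rho ** 2) * noise
        vol = np.full(parcels.grid.shape, np.nan)
        for i, label in enumerate(parcels.label_ids):
            vol[label_arr == label] = vec[i]
        maps.append(AnnotationMap(name=name, values=vol))
    return maps


# ---------------------------------------------------------------------------
# full dataset


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the complete synthetic study (deterministic in cfg)."""
    grid = make_grid(cfg)
    masks = make_tissue_masks(grid)
    brain, gm, wm, csf = masks
    network_masks = make_network_masks(grid)
    atlas = make_canonical_atlas(grid, gm)
    parcels = make_parcellation(grid, gm, cfg.n_parcels)
    scans = [generate_scan(cfg, i, grid=grid, masks=masks,
                           network_masks=network_masks)
             for i in range(cfg.n_subjects)]
    coords, targets = generate_coordinates(cfg, grid=grid,
                                           network_masks=network_masks,
                                           gm_mask=gm)
    net_vec = network_parcel_vector(network_masks["A"], parcels)
    annotations = generate_annotations(cfg, net_vec, parcels)
    return SyntheticDataset(config=cfg, grid=grid, scans=scans,
                            coordinates=coords, atlas=atlas, parcels=parcels,
                            annotations=annotations, brain_mask=brain,
                            gm_mask=gm, wm_mask=wm, csf_mask=csf,
                            network_masks=network_masks,
                            network_parcel_vec=net_vec,
                            contrast_targets=targets)
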