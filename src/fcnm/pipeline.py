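"""End-to-end orchestration: synth -> preprocess -> seeds -> FC ->
group network mapping -> canonical profile -> chemoarchitecture.

One :class:`RunConfig` captures every analysis constant (seed radius,
FDR q, overlap fraction, 10%-involvement rule, permutation count,
seeds and toggles); the run report echoes the full configuration and
records per-stage parameters, output digests and the final overlap
profile and chem results, so identical config + seed gives a
byte-identical JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .grid import VolumeGrid
from .io import CoordinateTable, LabelAtlas
from .seeds import build_contrast_seeds
from .preprocess import preprocess_scan, motion_exclusion
from .fc import fc_map
from .group import one_sample_t, fdr_threshold, overlap_map, OverlapProbabilityMap
from .networks import overlap_profile
from .chem import correlate_all, parcellate
from .synth import SyntheticConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "dice",
           "sensitivity_compare"]


@dataclass
class RunConfig:
    """All analysis parameters for one pipeline run."""

    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    radii_mm: tuple = (4.0,)          # e.g. (1.0, 4.0, 7.0) for sensitivity
    primary_radius_mm: float = 4.0
    q_level: float = 0.05
    overlap_fraction: float = 0.5
    significance_fraction: float = 0.10
    n_permutations: int = 5000
    chem_method: str = "spearman"
    chem_seed: int = 7
    n_drop: int = 10
    band: tuple = (0.01, 0.1)
    fwhm_mm: float = 6.0
    global_signal: bool = True

    def __post_init__(self):
        self.radii_mm = tuple(float(r) for r in self.radii_mm)
        if self.primary_radius_mm not in self.radii_mm:
            raise ValueError("primary_radius_mm must be one of radii_mm")
        if not (0 < self.q_level < 1 and 0 < self.overlap_fraction <= 1
                and 0 <= self.significance_fraction <= 1):
            raise ValueError("threshold out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = SyntheticConfig(**raw.pop("synth", {}))
        for key in ("radii_mm", "band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=synth, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["shape"] = list(self.synth.shape)
        d["radii_mm"] = list(self.radii_mm)
        d["band"] = list(self.band)
        return d


@dataclass
class PipelineResult:
    """In-memory results of a full run (the report is the JSON view)."""

    config: RunConfig
    dataset: SyntheticDataset
    preprocessed: list
    radius_results: dict       # radius -> {"seeds", "excluded", "binmaps", "overlap"}
    profile: object
    chem: object
    dice_matrix: list
    report: dict

    @property
    def final_mask(self) -> np.ndarray:
        return self.radius_results[self.config.primary_radius_mm]["overlap"].final_mask


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A&B| / (|A|+|B|); empty vs empty defined as 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def sensitivity_compare(masks) -> np.ndarray:
    """Pairwise Dice matrix over >= 2 masks on a common grid."""
    masks = [np.asarray(m).astype(bool) for m in masks]
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    n = len(masks)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dice(masks[i], masks[j])
    return out


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def preprocess_dataset(config: RunConfig, dataset: SyntheticDataset):
    """Motion-screen and preprocess every subject; returns
    (preprocessed list, exclusion records)."""
    preps, excluded = [], []
    for scan in dataset.scans:
        keep, qc = motion_exclusion(scan)
        if not keep:
            excluded.append({"subject_id": scan.subject_id, **qc})
            continue
        preps.append(preprocess_scan(
            scan, n_drop=config.n_drop, band=config.band,
            fwhm_mm=config.fwhm_mm, global_signal=config.global_signal))
    if len(preps) < 3:
        raise RuntimeError("fewer than 3 subjects survive motion screening")
    return preps, excluded


def network_mapping_at_radius(config: RunConfig, dataset: SyntheticDataset,
                              preprocessed: list, radius_mm: float) -> dict:
    """Seed construction, per-subject FC, group t + FDR, overlap map."""
    seeds, excluded = build_contrast_seeds(
        dataset.coordinates, dataset.grid, radius_mm=radius_mm,
        brain_mask=dataset.gm_mask)
    binmaps = []
    for seed in seeds:
        zmaps = [fc_map(prep, seed) for prep in preprocessed]
        tmap = one_sample_t(zmaps, contrast_id=f"{seed.study_id}/{seed.contrast_id}")
        binmaps.append(fdr_threshold(tmap, q=config.q_level,
                                     mask=dataset.brain_mask))
    overlap = overlap_map(binmaps, threshold_fraction=config.overlap_fraction)
    return {"seeds": seeds, "excluded": excluded, "binmaps": binmaps,
            "overlap": overlap}


def run_pipeline(config: RunConfig, dataset: SyntheticDataset | None = None,
                 preprocessed: list | None = None) -> PipelineResult:
    """Execute every stage in order and assemble the run report.

    *dataset* / *preprocessed* may be supplied to reuse earlier stages
    (any evaluation order gives identical results); by default both are
    generated from the config.
    """
    stage = "synthesize"
    try:
        if dataset is None:
            dataset = generate_dataset(config.synth)
        stage = "preprocess"
        if preprocessed is None:
            preprocessed, subj_excluded = preprocess_dataset(config, dataset)
        else:
            subj_excluded = []
        radius_results = {}
        for radius in config.radii_mm:
            stage = f"network_mapping(radius={radius:g}mm)"
            radius_results[radius] = network_mapping_at_radius(
                config, dataset, preprocessed, radius)
        stage = "canonical_profile"
        primary = radius_results[config.primary_radius_mm]["overlap"]
        profile = overlap_profile(primary.final_mask, dataset.atlas,
                                  config.significance_fraction)
        stage = "chemoarchitecture"
        network_vec = parcellate(primary.final_mask.astype(float), dataset.parcels)
        chem = correlate_all(network_vec, dataset.annotations,
                             scheme=dataset.parcels,
                             n_perm=config.n_permutations,
                             seed=config.chem_seed, method=config.chem_method)
        stage = "report"
        dice_matrix = (sensitivity_compare(
            [radius_results[r]["overlap"].final_mask for r in config.radii_mm]).tolist()
            if len(config.radii_mm) > 1 else [[1.0]])
        report = _build_report(config, dataset, preprocessed, subj_excluded,
                               radius_results, profile, chem, dice_matrix)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    return PipelineResult(config=config, dataset=dataset,
                          preprocessed=preprocessed,
                          radius_results=radius_results, profile=profile,
                          chem=chem, dice_matrix=dice_matrix, report=report)


def _build_report(config, dataset, preprocessed, subj_excluded, radius_results,
                  profile, chem, dice_matrix) -> dict:
    per_radius = {}
    for radius, res in radius_results.items():
        overlap: OverlapProbabilityMap = res["overlap"]
        per_radius[f"{radius:g}mm"] = {
            "n_contrasts": overlap.n_contrasts,
            "excluded_contrasts": res["excluded"],
            "seed_voxels": {f"{s.study_id}/{s.contrast_id}": s.n_voxels
                            for s in res["seeds"]},
            "suprathreshold_voxels": {b.contrast_id: b.n_suprathreshold
                                      for b in res["binmaps"]},
            "min_count": overlap.min_count,
            "final_mask_voxels": int(overlap.final_mask.sum()),
            "counts_digest": _digest(overlap.counts),
            "final_mask_digest": _digest(overlap.final_mask),
        }
    return {
        "config": config.to_dict(),
        "n_subjects_preprocessed": len(preprocessed),
        "subjects_excluded": subj_excluded,
        "qc": {p.subject_id: p.qc for p in preprocessed},
        "network_mapping": per_radius,
        "sensitivity_dice": dice_matrix,
        "overlap_profile": {
            "unassigned_voxels": profile.unassigned_voxels,
            "networks": [
                {k: (float(v) if isinstance(v, float) else v)
                 for k, v in rec.items()}
                for rec in profile.to_records()],
        },
        "chem": [
            {"name": r["name"], "r": float(r["r"]),
             "p_perm": float(r["p_perm"]), "p_fdr": float(r["p_fdr"]),
             "significant": bool(r["significant"])}
            for r in chem.to_dict(orient="records")],
    }


def report_json(report: dict) -> str:
    """Canonical JSON serialisation of a run report (byte-stable)."""
    return json.dumps(report, sort_keys=True, indent=1)
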