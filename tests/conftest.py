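import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fcnm import RunConfig, run_pipeline
from fcnm.grid import VolumeGrid
from fcnm.preprocess import PreprocessedScan
from fcnm.pipeline import preprocess_dataset
from fcnm.synth import SyntheticConfig, generate_dataset

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None)
settings.load_profile("suite")

logging.getLogger("fcnm").setLevel(logging.ERROR)

#: Seed of the canonical synthetic study used across the suite.
STUDY_SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """The default-condition synthetic study (20 subjects, 10 contrasts
    all targeting planted network A)."""
    return generate_dataset(SyntheticConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def multi_radius_run(default_dataset):
    """Full pipeline on the default study at seed radii 1, 4 and 7 mm."""
    cfg = RunConfig(synth=SyntheticConfig(seed=STUDY_SEED),
                    radii_mm=(1.0, 4.0, 7.0))
    preps, _ = preprocess_dataset(cfg, default_dataset)
    return run_pipeline(cfg, dataset=default_dataset, preprocessed=preps)


@pytest.fixture(scope="session")
def split_run(multi_radius_run):
    """Specificity conditions: contrasts split 40/40/20 across network A,
    network B and background gray matter (scans identical to the default
    study, so preprocessing is reused)."""
    cfg = RunConfig(synth=SyntheticConfig(seed=STUDY_SEED, scenario="split"),
                    radii_mm=(4.0,))
    ds = generate_dataset(cfg.synth)
    return run_pipeline(cfg, dataset=ds,
                        preprocessed=multi_radius_run.preprocessed)


def tiny_run_config(seed: int = 5) -> RunConfig:
    """A miniature but complete pipeline configuration (fast)."""
    return RunConfig(
        synth=SyntheticConfig(seed=seed, n_subjects=6, n_timepoints=80,
                              n_contrasts=4, n_parcels=50, amplitude=0.3),
        radii_mm=(4.0,), n_permutations=200)


def make_prep(bold: np.ndarray, tr: float = 1.0,
              usable_mask: np.ndarray | None = None) -> PreprocessedScan:
    """Wrap a raw 4-D array as a PreprocessedScan (for FC unit tests)."""
    grid = VolumeGrid.isotropic(bold.shape[:3], 3.0, centered=False)
    if usable_mask is None:
        usable_mask = np.ones(bold.shape[:3], dtype=bool)
    return PreprocessedScan(subject_id="toy", bold=np.asarray(bold, float),
                            usable_mask=usable_mask,
                            fd=np.zeros(bold.shape[3]), qc={}, tr=tr, grid=grid)
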