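"""Confound-removal chain: FD, motion screening, nuisance design,
regression, bandpass and smoothing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fcnm.grid import VolumeGrid
from fcnm.io import SubjectScan
from fcnm.preprocess import (bandpass, build_nuisance_design,
                             drop_initial_volumes, framewise_displacement,
                             friston24, motion_exclusion, preprocess_scan,
                             regress_and_filter, residualize, smooth)
from fcnm.synth import SyntheticConfig, generate_scan


def make_scan(T=60, shape=(8, 8, 8), tr=1.0, seed=0, motion=None):
    rng = np.random.default_rng(seed)
    grid = VolumeGrid.isotropic(shape, 3.0, centered=False)
    masks = np.zeros(shape, dtype=bool)
    brain = masks.copy()
    brain[1:-1, 1:-1, 1:-1] = True
    gm = brain.copy()
    wm = np.zeros(shape, dtype=bool)
    wm[3:5, 3:5, 3:5] = True
    csf = np.zeros(shape, dtype=bool)
    csf[2, 2, 2] = True
    gm &= ~wm & ~csf
    if motion is None:
        motion = np.zeros((T, 6))
    return SubjectScan(subject_id="t", bold=rng.standard_normal(shape + (T,)),
                       motion=motion, brain_mask=brain, gm_mask=gm,
                       wm_mask=wm, csf_mask=csf, tr=tr, grid=grid)


class TestVolumeDropAndFD:
    def test_drop_truncates_bold_and_motion(self):
        scan = make_scan(T=100)
        out = drop_initial_volumes(scan, 10)
        assert out.n_timepoints == 90 and out.motion.shape == (90, 6)

    def test_drop_zero_is_identity(self):
        scan = make_scan(T=20)
        assert drop_initial_volumes(scan, 0) is scan

    def test_drop_too_many_raises(self):
        with pytest.raises(ValueError, match="drop"):
            drop_initial_volumes(make_scan(T=5), 10)

    def test_zero_motion_gives_zero_fd(self):
        assert np.all(framewise_displacement(np.zeros((20, 6))) == 0)

    def test_translation_step_closed_form(self):
        """A 0.5-mm step in x produces FD exactly 0.5 at that volume."""
        motion = np.zeros((10, 6))
        motion[5:, 0] = 0.5
        fd = framewise_displacement(motion)
        expected = np.zeros(10)
        expected[5] = 0.5
        assert np.allclose(fd, expected)

    def test_rotation_step_uses_50mm_arc(self):
        """A 0.01-rad rotation step maps to 0.5 mm on the 50-mm sphere."""
        motion = np.zeros((10, 6))
        motion[5:, 4] = 0.01
        fd = framewise_displacement(motion)
        assert fd[5] == pytest.approx(0.5)
        assert fd[0] == 0.0

    @given(st.integers(0, 500))
    def test_fd_invariant_to_constant_offset(self, seed):
        rng = np.random.default_rng(seed)
        motion = rng.normal(0, 0.1, size=(30, 6))
        offset = rng.normal(0, 5, size=6)
        assert np.allclose(framewise_displacement(motion),
                           framewise_displacement(motion + offset), atol=1e-12)

    def test_nonfinite_motion_rejected(self):
        motion = np.zeros((10, 6))
        motion[3, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            framewise_displacement(motion)


class TestMotionExclusion:
    @pytest.mark.parametrize("trans, rot_deg, keep", [
        (1.9, 1.9, True),
        (2.1, 0.0, False),
        (0.0, 2.0, True),    # "not exceeding" keeps equality
        (0.0, 2.0001, False),
    ])
    def test_threshold_convention(self, trans, rot_deg, keep):
        motion = np.zeros((20, 6))
        motion[10, 0] = trans
        motion[12, 4] = np.radians(rot_deg)
        scan = make_scan(T=20, motion=motion)
        decision, qc = motion_exclusion(scan)
        assert decision is keep
        assert qc["max_translation_mm"] == pytest.approx(trans)


class TestNuisanceDesign:
    def test_column_count_without_spikes(self):
        """drift(1) + Friston-24 + global/wm/csf(3) = 28 columns."""
        design = build_nuisance_design(make_scan(T=40))
        assert design.n_columns == 28

    def test_spike_columns_are_one_hot(self):
        motion = np.zeros((40, 6))
        motion[10, 0] = 0.6   # impulse -> FD > 0.5 at volumes 10 and 11
        design = build_nuisance_design(make_scan(T=40, motion=motion))
        spikes = [n for n in design.column_names if n.startswith("spike")]
        assert spikes == ["spike_010", "spike_011"]
        assert design.n_columns == 30
        for name in spikes:
            col = design.matrix[:, design.column_names.index(name)]
            assert col.sum() == 1.0 and set(np.unique(col)) == {0.0, 1.0}

    def test_fd_exactly_at_threshold_is_not_a_spike(self):
        motion = np.zeros((40, 6))
        motion[10:, 0] = 0.5  # step: FD exactly 0.5, strict > keeps it out
        design = build_nuisance_design(make_scan(T=40, motion=motion))
        assert not any(n.startswith("spike") for n in design.column_names)

    def test_friston24_layout(self):
        motion = np.arange(60, dtype=float).reshape(10, 6)
        f = friston24(motion)
        assert f.shape == (10, 24)
        assert np.allclose(f[0, 6:12], 0)          # lagged zeros at t=0
        assert np.allclose(f[:, 12:18], motion ** 2)

    def test_empty_tissue_mask_raises(self):
        scan = make_scan(T=30)
        scan.csf_mask[:] = False
        with pytest.raises(ValueError, match="csf"):
            build_nuisance_design(scan)


class TestRegressionAndFilter:
    def test_design_column_is_annihilated(self):
        scan = make_scan(T=50)
        design = build_nuisance_design(scan)
        data = np.column_stack([design.matrix[:, 3],
                                design.matrix[:, 3] * 2 + 1])
        resid = residualize(data, design)
        assert np.abs(resid).max() < 1e-10

    def test_residualization_is_idempotent(self):
        scan = make_scan(T=50, seed=2)
        design = build_nuisance_design(scan)
        data = scan.bold.reshape(-1, 50).T
        once = residualize(data, design)
        twice = residualize(once, design)
        assert np.allclose(once, twice, atol=1e-8)

    def test_residuals_uncorrelated_with_every_column(self):
        scan = make_scan(T=50, seed=3)
        design = build_nuisance_design(scan)
        resid = residualize(scan.bold.reshape(-1, 50).T, design)
        norms = np.linalg.norm(resid, axis=0)
        # voxels fully explained by the design (e.g. the CSF voxel itself)
        # have ~zero residuals; their correlation is undefined
        informative = norms > 1e-8
        for j in range(design.n_columns):
            col = design.matrix[:, j] - design.matrix[:, j].mean()
            if np.linalg.norm(col) == 0:
                continue
            corr = (resid[:, informative].T @ col) / (
                norms[informative] * np.linalg.norm(col))
            assert np.abs(corr).max() < 1e-8

    def test_collinear_columns_dropped_with_warning(self):
        T = 30
        x = np.random.default_rng(0).standard_normal(T)
        design = np.column_stack([x, 2 * x])
        data = np.random.default_rng(1).standard_normal((T, 4))
        with pytest.warns(UserWarning, match="collinear"):
            residualize(data, design)

    def test_inband_sinusoid_passes(self):
        t = np.arange(200)
        wave = np.sin(2 * np.pi * 0.05 * t)   # exactly on an FFT bin
        out = bandpass(wave[None, :], tr=1.0)[0]
        assert out.std() / wave.std() >= 0.99

    def test_out_of_band_sinusoid_attenuated(self):
        t = np.arange(200)
        wave = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass(wave[None, :], tr=1.0)[0]
        assert out.std() <= 0.01 * wave.std()

    def test_band_edges_inclusive(self):
        t = np.arange(200)
        for f in (0.01, 0.1):   # both edges sit on exact bins of 200 x 1 s
            wave = np.cos(2 * np.pi * f * t)
            out = bandpass(wave[None, :], tr=1.0)[0]
            assert out.std() / wave.std() >= 0.99


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        vol = np.random.default_rng(0).standard_normal((9, 9, 9))
        assert np.array_equal(smooth(vol, 0.0, 3.0), vol)

    def test_delta_matches_analytic_kernel(self):
        """Smoothing a delta reproduces the separable discrete Gaussian."""
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        fwhm, voxel = 6.0, 3.0
        out = smooth(vol, fwhm, voxel)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
        radius = int(4 * sigma + 0.5)
        k = np.exp(-np.arange(-radius, radius + 1) ** 2 / (2 * sigma ** 2))
        k /= k.sum()
        expected = np.einsum("i,j,k->ijk", k, k, k)
        lo, hi = 7 - radius, 7 + radius + 1
        assert np.allclose(out[lo:hi, lo:hi, lo:hi], expected, atol=1e-6)

    def test_interior_delta_sum_preserved(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        assert smooth(vol, 6.0, 3.0).sum() == pytest.approx(1.0, abs=1e-6)


class TestFullChain:
    def test_chain_is_deterministic(self):
        cfg = SyntheticConfig(seed=3, n_subjects=1, n_timepoints=60)
        scan = generate_scan(cfg, 0)
        a = preprocess_scan(scan, n_drop=10)
        b = preprocess_scan(generate_scan(cfg, 0), n_drop=10)
        assert np.array_equal(a.bold, b.bold)
        assert a.qc == b.qc

    def test_regress_and_filter_annihilates_nuisance_prefilter(self):
        scan = drop_initial_volumes(make_scan(T=60, seed=4), 10)
        design = build_nuisance_design(scan)
        resid = residualize(scan.bold.reshape(-1, 50).T, design)
        # the projection step itself (pre-filter) leaves zero correlation
        proj = design.matrix.T @ resid
        assert np.abs(proj).max() < 1e-8
        filtered = regress_and_filter(scan, design)
        assert filtered.shape == scan.bold.shape

    def test_qc_counts_spikes(self):
        motion = np.zeros((60, 6))
        motion[30, 1] = 0.7
        scan = make_scan(T=60, motion=motion)
        prep = preprocess_scan(scan, n_drop=10)
        assert prep.qc["n_spikes"] == 2  # impulse crosses 0.5 mm twice
        assert prep.fd[0] == 0.0
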