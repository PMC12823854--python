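# Methods

## The mapping procedure

`fcnm` localises the convergent functional network behind a set of
published gray-matter coordinates.  The model is deliberately simple:
a contrast seed is the union of small spheres around one study's
peaks; connectivity is plain Pearson correlation of the mean seed time
series with every brain voxel, Fisher z-transformed so that per-voxel
values are approximately normal with variance 1/(T−3); group inference
is a voxelwise one-sample t-test over subjects with one-sided p-values
(only positive connectivity is propagated, since the sign of negative
resting-state correlations is analytically ambiguous after global
signal regression); multiplicity is handled by voxel-level
Benjamini–Hochberg FDR rather than cluster inference, trading
sensitivity for spatial precision; and convergence across studies is
the literal "at least 50% of contrasts" count rule,
`counts ≥ ceil(0.5·n)`.

Assumptions worth making explicit:

- All volumes already sit on one common grid (default 3-mm isotropic);
  registration, segmentation and slice-timing are upstream problems.
- Each study contributes one contrast; coordinate sign (GM increase
  vs decrease) is not used.
- Contrasts whose coordinates produce an empty seed after gray-matter
  masking are excluded but *surviving* contrasts with empty
  FDR-thresholded maps still count in the 50% denominator.
- Talairach coordinates are converted with the Lancaster
  (`icbm_spm2tal`) affine, inverted; the matrix is an explicit,
  swappable constant because published studies rarely state their
  converter.

## Confound removal

The micro-preprocessing chain operates per subject on (X,Y,Z,T)
arrays: drop the first 10 volumes; Power framewise displacement
(backward differences, rotations × 50 mm); exclusion when any
|translation| > 2 mm or |rotation| > 2° (equality keeps the subject —
"not exceeding"); OLS residualisation against linear drift, the
Friston-24 expansion (current, lagged, both squared), one-hot spike
regressors at FD > 0.5 mm (strict inequality), and global/WM/CSF mean
signals (global on by default); an ideal rectangular FFT bandpass
retaining [0.01, 0.1] Hz inclusive; then separable Gaussian smoothing
with σ = FWHM/(2√(2 ln 2)) per axis.  Regression precedes filtering in
a single pass; the known caveat — regressors are not band-limited, so
filtering can reintroduce a minute component of removed variance — is
accepted for fidelity to the standard toolbox ordering.  Collinear
design columns (e.g. all-zero motion expansions of a motionless scan)
are dropped with a warning before the fit.

## Key parameters

| parameter | default | role |
|---|---|---|
| seed radius | 4 mm (1, 7 sensitivity) | sphere size around each peak |
| FDR q | 0.05 | voxel-level threshold of group t-maps |
| overlap fraction | 0.5 | "connected to ≥ 50% of contrast seeds" |
| involvement rule | ≥ 0.10 (inclusive) | canonical-network classification |
| bandpass | 0.01–0.1 Hz | resting-state fluctuation band |
| smoothing | 6 mm FWHM | spatial SNR pooling |
| spike threshold | FD > 0.5 mm | scrubbing via spike regressors |
| permutations | 5,000 | chem null distribution |

Numerical conventions: mm→voxel rounding is half-away-from-zero
(deterministic tie-breaks for seed masks); sphere membership uses
≤ radius; correlations are clipped to |r| ≤ 1−1e−7 before atanh so
seed self-correlations stay finite; zero-variance voxels are NaN and
excluded from the FDR pool; sd = 0 voxels in the t-test take t = ±inf
(p = 0/1) rather than NaN because synthetic data can produce them
legally; the 50% count uses `ceil(fraction·n − 1e−9)` to guard float
noise; p-values from permutation use the add-one estimator, so
p ≥ 1/(B+1) always.

A consequence of drawing spheres literally in mm space: a 1-mm sphere
on a 3-mm grid covers a voxel only when the coordinate falls within
1 mm of its centre, so at the 1-mm sensitivity radius many spheres are
empty and contrasts can drop out (all exclusions are logged and
reported).  The mapping at that radius therefore rests on fewer
contrasts and is intrinsically noisier — which is exactly what the
radius sensitivity analysis is meant to surface.

## Chemoarchitecture

The binary network map and every annotation volume are reduced to a
gray-matter parcellation by within-parcel means (the network map thus
becomes a coverage fraction per parcel).  The association statistic is
Spearman's ρ by default — annotation maps are tracer-scaled and only
their ordinal structure is trusted — with Pearson available by
configuration.  Significance uses an exchangeable parcel-label
permutation null, two-sided, add-one corrected, then BH-FDR across the
map set.  The exchangeable null ignores spatial autocorrelation; an
order-preserving cyclic-rotation null (`null="rotation"`) is exposed
as a conservative alternative for smooth maps.  A true
surface-spin test requires spherical geometry the volumetric toy
parcellation does not have.

## The synthetic connectome

The generator produces every pipeline input with known ground truth,
at desk scale: 24³ voxels of 3 mm, 20 subjects, 210 volumes at
TR = 0.72 s (HCP-like), 10 contrasts of 3 coordinates.

Geometry: a spherical "brain" of radius 33 mm with concentric CSF
(≤ 4 mm) and WM (4–8 mm) cores and a gray-matter shell; a planted
network is a union of 11-mm spherical nodes centred 20 mm from the
origin along cube-vertex directions, so each node sits inside exactly
one octant of the shell.  The toy canonical atlas labels those eight
octants with the seven standard cortical network names plus a
subcortical label; network A's three nodes occupy the octants named
VentralAttention, Frontoparietal and DefaultMode, network B's two
nodes the Visual and Subcortical octants.  The parcellation splits the
shell into 100 raster-ordered, near-equal parcels.

Signal: unit-variance white voxel noise plus, per planted network, a
shared subject-specific latent band-limited to 0.01–0.1 Hz and scaled
by `amplitude`.  Band-limiting the latent inside the analysis passband
separates pipeline correctness from filter attenuation.  Motion is a
Gaussian random walk (0.01 mm / 2·10⁻⁴ rad steps); spike events
(p = 0.02 per volume) add a one-volume 0.6-mm translation impulse —
two FD > 0.5 mm frames — and a coincident global intensity offset, so
spike regression has real work to do.

The default amplitude of 0.06 (noise sd 1) was set by design
calculation, not fitting: after bandpass (≈ 13 of 100 retained bins)
and 6-mm smoothing, it puts seed-to-network correlations near 0.3–0.4
— weak but reliably detectable with 20 subjects — while keeping the
smoothing-induced halo around the planted nodes below about one
voxel, so recovered-mask Dice against ground truth is a meaningful
statistic.  Substantially larger amplitudes make the halo itself
significant and *reduce* spatial fidelity; the miniature configs used
in plumbing tests (6 subjects, 70 usable volumes) raise the amplitude
to 0.3 because the default is undetectable at that size.

Annotation maps are built at parcel level as
ρ·z(coverage_A) + √(1−ρ²)·noise and broadcast to voxels; by default
the maps named 5HT2A, CB1 and mGluR5 are coupled at ρ = 0.6 and the
remaining 27 are pure noise, emulating a study in which three receptor
systems genuinely co-localise with the mapped network.

What the generator does **not** emulate: hemodynamics, physiological
noise spectra, anatomical geometry, spatial noise correlations beyond
those induced by smoothing, distance-dependent connectivity, or
realistic receptor-map autocorrelation.  Passing tests therefore
demonstrate correctness of the pipeline's statistics and bookkeeping
under a known generative model — not performance on real fMRI.

## Problem sizes used in the checks

The recovery/robustness checks run the complete pipeline at the
default conditions above (≈ 20 s).  Calibration checks use 200 null
replicates at B = 500 permutations, P = 100 parcels for the empirical
test size and the 30-map FDR family-error rate, and 50 repeats at
B = 2,000 for the ρ = 0.6 power check.  Determinism is verified by
running a small full pipeline twice and comparing the serialized run
reports byte for byte.

## Known limitations

- The FDR pool is an explicit mask input; whole-brain vs gray-matter
  pooling changes voxel counts and is the caller's choice (default:
  whole brain, seeds restricted to gray matter).
- One-sided inference means genuinely negative convergent FC is
  invisible by design.
- The exchangeable chem null is anticonservative for spatially smooth
  real annotation maps; use the rotation null or an external spin
  test for surface data.
- The per-voxel t-test df shrinks when subjects contribute NaN voxels;
  the report's nominal df refers to the full-subject case.
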