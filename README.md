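# fcnm — coordinate-based functional connectivity network mapping

Voxel-based morphometry studies of the same trait or disorder often
report scattered, poorly replicating gray-matter coordinates.
Functional connectivity network mapping (FCNM) asks a different
question: do those heterogeneous coordinates land on a *common
functional network*?  Each study's peaks are turned into a small seed
mask, the seed's resting-state connectivity map is computed in every
subject of a normative cohort, group maps are thresholded, and the
voxels connected to a majority of study seeds form the convergent
network.  That network is then profiled against canonical brain
networks (default mode, frontoparietal, ventral attention, ...) and
against PET-derived neurotransmitter receptor/transporter maps.

`fcnm` implements this pipeline end to end for researchers in
personality/clinical network neuroscience, together with a fully
synthetic connectome generator so that every stage can be validated
against known ground truth without access to restricted cohort data.

## Method

For contrast *c* with reported MNI peaks {x₁…x_k} (Talairach peaks are
converted with the Lancaster affine):

1. **Seed**: S_c = ⋃ᵢ {v : ‖v − xᵢ‖ ≤ r} ∩ GM, default r = 4 mm
   (sensitivity: 1 and 7 mm).
2. **Subject FC**: for subject *s*, z_cs(v) = atanh ρ(ȳ_{S_c}, y_v) —
   Pearson correlation of the mean seed time series with every voxel,
   Fisher z-transformed.  Input data are confound-cleaned: first 10
   volumes dropped, Friston-24 motion expansion + linear drift +
   FD > 0.5 mm spike indicators + global/WM/CSF signals regressed out,
   ideal 0.01–0.1 Hz bandpass, 6-mm FWHM Gaussian smoothing; subjects
   moving > 2 mm / 2° are excluded (framewise displacement uses
   Power's formula with a 50-mm rotation radius).
3. **Group map**: voxelwise one-sample t over subjects; one-sided p
   (positive FC only); voxel-level Benjamini–Hochberg FDR at q = 0.05;
   binarize.
4. **Overlap map**: counts(v) = Σ_c 1[v ∈ network_c]; final mask =
   {v : counts(v) ≥ ⌈0.5 · n_contrasts⌉}.
5. **Canonical profile**: for each canonical network N,
   overlap(N) = |final ∩ N| / |N|; networks with ≥ 10% are "involved".
6. **Chemoarchitecture**: the final mask and each of 30 annotation maps
   are averaged within a gray-matter parcellation; Spearman ρ per map,
   two-sided permutation p over 5,000 parcel-label permutations
   (add-one corrected), BH-FDR across the 30 maps, significance at
   p_FDR < 0.05.

## Worked example

```python
from fcnm import RunConfig, run_pipeline, dice
from fcnm.synth import SyntheticConfig

cfg = RunConfig(synth=SyntheticConfig(seed=1), radii_mm=(1.0, 4.0, 7.0))
result = run_pipeline(cfg)          # ~20 s: 20 subjects, 10 contrasts, 24^3 grid

truth = result.dataset.network_masks["A"]
print(dice(result.final_mask, truth))                # 0.930
print(result.profile.significant_networks())
# ['VentralAttention', 'Frontoparietal', 'DefaultMode']
print(result.chem[result.chem.significant][["name", "r", "p_perm", "p_fdr"]])
#       name         r    p_perm     p_fdr
# 2    5HT2A  0.534234  0.000200  0.005999
# 6      CB1  0.307785  0.002599  0.025995
# 17  mGluR5  0.377471  0.000400  0.005999
```

The synthetic study plants a three-node network ("A") inside the
octants labelled VentralAttention, Frontoparietal and DefaultMode of a
toy canonical atlas, seeds all 10 contrasts inside it, and couples
three annotation maps (5HT2A, CB1, mGluR5) to the planted network at
ρ = 0.6.  The run above recovers the planted network at Dice 0.93,
classifies exactly those three canonical systems as involved (~31–33%
overlap each, all others 0%), and flags exactly the three coupled
receptor maps after FDR — the qualitative signature the method is
designed to produce.  A 40/40/20 split of contrasts across two
networks leaves both below the 50% threshold (max coverage < 1%),
demonstrating specificity.

The same run is available from the shell:

```bash
fcnm run --config run.yaml --out run_report.json   # full pipeline
fcnm synth / seeds / preprocess / fc / network / profile / chem ...
```

Every run writes a JSON report echoing the complete configuration and
per-stage digests; identical config + seed gives a byte-identical
report.

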