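# synfp

Nanoscale synapse analysis for expansion microscopy (ExM) and ExM-STED
data, with a synthetic-data generator that emulates the imaging data with
known ground truth.

## What it is for

Tenfold expansion microscopy turns the postsynaptic density (PSD) of an
excitatory synapse into a micron-scale object that a confocal microscope can
segment in 3D, and ExM combined with STED resolves the subsynaptic particle
mosaics within it. Quantifying such data needs four connected pieces, which
this package provides as a library plus a thin CLI:

1. **Expansion quality control** (`synfp.expansion_qc`) — the peak-to-peak
   distance between the presynaptic active zone (AZ) and the PSD, read from
   line profiles across side-view synapses, is a local ruler for the
   expansion factor. Distances are measured per profile (polynomial fit,
   two dominant peaks, local quadratic refinement), averaged per animal and
   normalized to the batch mean; the resulting per-animal **correction
   factor** divides every downstream length (areas by its square, volumes
   by its cube).
2. **3D scaffold shape fingerprinting** (`synfp.scaffold_shapes`,
   `synfp.fingerprint`) — probability maps of immunolabeled scaffolds
   (43 × 43 × 120 nm voxels) are thresholded (≥ 0.2), segmented with
   26-connectivity, border-touching objects excluded, and objects below a
   200-voxel threshold (a cuboid of twice the confocal resolution limit,
   2 × 200² × 500 nm³ = 180.3 voxels, rounded to 200) rejected. Each object
   yields 9 features: volume (nm³), smoothed-mesh surface (nm²), volume
   ratio against its moment-equivalent ellipsoid, sphericity
   π^⅓(6V)^⅔ / A, and five scale/translation/rotation-invariant second-order
   moment descriptors M1–M5. Features are log-transformed, z-scored,
   reduced to PC1–3, clustered with CLARA (k-medoids on repeated
   subsamples), the cluster number selected by the Gap statistic
   (firstSEmax), clusters reordered by medoid volume, and a principal curve
   through the ordered medoids assigns each scaffold a **pseudotime** — an
   ordinal proxy for synaptic maturity along the small-spherical →
   voluminous-complex continuum.
3. **2D subsynaptic particle analysis** (`synfp.mosaic_particles`) —
   per-synapse en-face STED stacks (25 nm pixels) are rolling-ball
   background-subtracted, maximum-projected, rigidly aligned across
   channels, and particles detected by local-maxima region growing with
   saddle-based merging. Outputs per synapse: size/intensity/density,
   Manders colocalization M1/M2, mean k-nearest-neighbor distances,
   Ripley's K up to 500 nm with a summed CSR-deviation scalar, and
   center-of-mass distances of overlapping particle pairs across channels.
4. **Statistics** (`synfp.stat_engine`) — chi-square tests of independence
   with standardized-residual post hocs, the semi-parametric one-way MANOVA
   based on the modified ANOVA-type statistic (MATS) with
   parametric-bootstrap p-values, mixed-design repeated-measures ANOVA for
   NND profiles, two-sample Wilcoxon rank-sum tests, and Bonferroni /
   Benjamini–Hochberg adjustment.

Because no public imaging data accompanies this kind of study, the
synthetic generator (`synfp.synthgen`) is a first-class citizen: it emits
seeded profiles, 3D probability maps built from a constructive-geometry
morphology continuum, and two-channel particle mosaics (CSR /
Thomas-clustered / hard-core, with optional cross-channel pairing at a
fixed nm offset), each with complete ground-truth tables, so every pipeline
stage can be validated by parameter recovery.

## Worked example

```python
import pandas as pd
from synfp.synthgen import SimConfig, gen_profiles
from synfp import expansion_qc as eq

cfg = SimConfig(seed=1, n_profiles=20)
traces, truth = gen_profiles(cfg, animals={"A1": "B1", "A2": "B1"},
                             separations={"A1": 536.7, "A2": 524.0})
dist = pd.DataFrame([{"animal": t.animal, "batch": t.batch,
                      "distance_nm": eq.measure_az_psd(t)} for t in traces])
summary = eq.summarize_expansion(dist)
print(summary.animal_means.round(1))
print(summary.correction_factors.round(4))
```

prints

```
animal
A1    537.0
A2    524.1
Name: distance_nm, dtype: float64
animal
A1    1.0121
A2    0.9879
dtype: float64
```

The measured AZ–PSD means recover the planted separations (536.7 and
524.0 nm) to within a few tenths of a nanometer at 2% amplitude noise; the
correction factors (animal mean / batch mean) say that lengths measured in
animal A1 must be divided by 1.0121 — its tissue expanded 1.2% more than
the batch average — before animals are compared.

A full synthetic run (simulate → QC → shapes → fingerprint → particles →
stats → report) is one call:

```bash
synfp run-all --seed 5 --out runs/demo
```

which writes CSV tables, a plain-text log with filter accounting, and
`report.md` with the chi-square cluster-composition test, the MATS MANOVA,
the NND repeated-measures ANOVA, and the CSR-deviation rank-sum test.

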