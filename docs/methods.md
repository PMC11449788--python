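# Methods

This note documents the models, estimators and numerical choices behind
`synfp`, and what the synthetic-data generator does and does not emulate.

## Expansion quality control

**Model.** A side-view synapse produces a 1D intensity profile with two
dominant peaks — the active zone (AZ) and the postsynaptic density (PSD).
Their peak-to-peak distance in expanded units acts as a local expansion
ruler: at roughly tenfold expansion it sits near 510–540 nm.

**Measurement.** `measure_az_psd` fits a polynomial (degree 8 by default)
through the samples and takes the interior local maxima of the fit. Maxima
whose raw-trace height above the trace minimum is below 20% of the largest
are discarded as polynomial ringing; of the remainder the two highest are
kept (AZ and PSD dominate the profile by construction). Each peak is then
refined by a parabola fitted to the raw samples in a ±3-sample window
centered on the local raw maximum — for a symmetric peak sampled on-grid the
vertex is exact, which is why noiseless recovery is sub-nanometer and the
degree of the global polynomial barely matters. If the polynomial yields
fewer than two usable maxima the two highest separated raw maxima are used;
failing that the trace is flagged with a `MeasurementError` and excluded.
The measurement is invariant to constant baseline shifts and uniform
intensity scaling.

**Aggregation.** Distances are averaged per animal; a batch mean is the mean
of its member animals' means (so unequal profile counts per animal do not
bias the batch); the correction factor of an animal is animal mean / batch
mean. Downstream, lengths are divided by the factor, areas by its square,
volumes by its cube, and densities multiplied by its square. The direction
of the normalization (divide by the animal/batch ratio) is a package
convention, recorded here because the verbal description of such a rule is
ambiguous; it is config-exposed in the pipeline.

## Scaffold segmentation and the 9-feature shape set

Probability maps are thresholded at cutoff 0.2 (a voxel is kept when its
probability is **at or above** the cutoff; only values below are excluded),
components are labeled with 26-connectivity, and any component touching a
volume face is flagged and excluded — its shape is censored by the field of
view. Objects smaller than 200 voxels are rejected; the threshold is the
volume of a cuboid with edges of twice the lateral/axial confocal
resolution limit, 2 × 200² × 500 nm³ = 180.3 voxels at 43 × 43 × 120 nm,
rounded to the nearest hundred.

Per object:

* **volume** = voxel count × 43 × 43 × 120 nm³, divided by the cubed
  correction factor.
* **surface** = area of the 0.5 iso-surface extracted by marching cubes
  from the Gaussian-smoothed (sd 1 voxel) binary mask, at the true
  anisotropic voxel spacing. Smoothing the field before meshing removes the
  staircase overestimate of a binary mesh; digitized balls come out within
  ~2% of 4πr². Meshing with the anisotropic spacing (rather than converting
  with the lateral pixel size alone) keeps the surface physically consistent
  with the volume, so sphericity of a ball is ≈ 1 — the package treats this
  consistency as non-negotiable, since sphericity and the volume ratio are
  defined through it. Objects too small for the smoothed field to reach the
  iso-level fall back to the binary mesh; they are far below the volume
  filter anyway.
* **volume ratio** = |object △ E| / |object| on the voxel grid, where E is
  the moment-equivalent solid ellipsoid (same centroid, principal axes from
  the second central moments, semi-axes √(5λᵢ)). It is 0 when the object
  equals its fitted ellipsoid and grows as lobes or perforations develop.
* **sphericity** = π^⅓ (6V)^⅔ / A on the unnormalized physical V and A.
* **M1–M5**: with scale-normalized central moments
  η_pqr = μ_pqr / μ₀₀₀^(1+(p+q+r)/3) computed in physical coordinates with
  the voxel volume as measure, and H the 3×3 normalized second-moment
  matrix: M1 = tr H, M2 = sum of the 2×2 principal minors, M3 = det H,
  M4 = M1²/M2, M5 = M1³/M3. All five are exactly invariant to translation
  and to rotations that map the grid onto itself, and invariant to uniform
  scaling up to digitization (≤ 2% on objects of ≥ 10³ voxels). They are
  functions of the moment ellipsoid only, i.e., they measure departure of
  the mass distribution from its equivalent ellipsoid; M2–M4 co-vary
  strongly with M1 on elongation continua, which is why the MANOVA excludes
  M2–M4 by default. The concrete invariant set is config-visible
  (`FEATURE_COLUMNS`) because different 3D measurement suites define
  "five 3D moments" differently.
* Degenerate (coplanar) objects get a regularized moment matrix and a
  `degenerate` flag instead of NaNs.

## Fingerprinting

Features are log-transformed — log(x + ε) with ε = 10⁻⁶ of the feature's
smallest positive value, since the volume ratio can be exactly 0 — then
centered, scaled and reduced to the first three principal components. The
stored transform reproduces scores exactly, so downstream labels can be
mapped back onto raw records.

**CLARA.** k-medoids via PAM (greedy build + exhaustive swap) on each of 50
subsamples of size 40 + k; the medoid set with the smallest total Euclidean
dissimilarity over the full dataset is kept. Medoids are always real
objects.

**Gap statistic.** W_k is the total within-cluster sum of squared distances
to cluster centroids. B reference datasets (default 50) are drawn uniformly
over the bounding box of the PC scores (the scores are PCA-aligned by
construction). Gap(k) = mean_b log W_k(ref_b) − log W_k(data), with
SE_k = sd_b × √(1 + 1/B). The selection rule is firstSEmax: find the first
local maximum of the gap curve (the k before the first decrease) and take
the smallest k whose gap is within one SE of it.

**Cluster order and pseudotime.** Clusters are renumbered by ascending
medoid volume, so identity runs along the maturity continuum (volume rises
with cluster identity). A principal curve is initialized on the polyline
through the ordered medoids and refined by project → smooth-against-arc-length
→ reproject iterations (running-mean smoother with a window of 20% of the
sample, curve resampled to 100 control points, max 30 iterations, relative
tolerance 10⁻⁴; non-convergence returns the last iterate with a warning).
Points projecting beyond the curve ends are extrapolated along the terminal
segments so their ordering is preserved. Pseudotime is the arc-length
position, centered and scaled to unit SD.

## Particle analysis

Stacks (5–8 slices) are background-subtracted per slice with a rolling ball
(radius 10 px), maximum-projected, and cleared outside the synapse ROI.
Channel alignment is an exhaustive rigid search (integer translations
±10 px, rotations ±10° in 1° steps) maximizing Pearson correlation inside
the ROI; the identity is in the search space, so alignment never reduces
the correlation, and a flat channel returns the identity with a warning.

Detection is in the spirit of seeded region growing on peaks: Gaussian
presmooth (sd 1 px), local maxima inside the detection mask, watershed on
the inverted smoothed image, then iterative merging — a region is absorbed
by its neighbor over the highest saddle while its peak's height above that
saddle is below 20% of the peak height, or while the region is smaller than
4 px. Particle marks (area, total/average intensity) come from the raw
image; centroids are intensity-weighted.

Manders coefficients are computed on the particle-support masks:
M1 = Σ ch1 over (mask1 ∩ mask2) / Σ ch1 over mask1, and symmetrically M2.
Restricting the numerator to the intersection keeps both coefficients in
[0, 1] regardless of background outside a channel's own mask.

NND profiles are mean distances to the k nearest neighbors (k up to 20);
patterns with n ≤ K are computed to k = n − 1 and flagged truncated.
Ripley's K uses K̂(r) = |W| / (n(n−1)) Σ_{i≠j} w_ij 1(d_ij ≤ r) with the
isotropic edge correction — w_ij is the reciprocal fraction of the circle of
radius d_ij around point i lying inside the ROI window, evaluated by
angular sampling (180 angles; circles entirely inside the window shortcut
to weight 1). Radii run in 1 px steps to 20 px = 500 nm. The CSR-deviation
scalar is Σ_r (K̂(r) − πr²) / #radii: positive for clustering, negative for
inhibition, and calibrated to mean ≈ 0 under CSR (checked against a
999-replicate Monte-Carlo null). An uncorrected mode exists for oracle
tests. Overlapping particle pairs across channels are all (region in
mask 1, region in mask 2) pairs sharing at least one pixel — a region with
several partners contributes one pair per partner — and the reported value
is the mean center-of-mass distance.

## Statistics

* **Chi-square independence** (no continuity correction) with per-cell
  standardized residuals (O−E)/√(E(1−p_row)(1−p_col)), two-sided normal
  p-values Bonferroni-corrected by the cell count, and optional pairwise
  column tests Bonferroni-corrected over pairs.
* **MATS MANOVA**: Q_N = N ȳᵀ T (T D̂_N T)⁺ T ȳ with T = (I_a − J_a/a) ⊗ I_p
  and D̂_N the diagonal of the block-diagonal covariance of the stacked
  group means (group covariances scaled by N/n_i). No multivariate
  normality or covariance homogeneity is assumed; the statistic is
  invariant to per-variable rescaling. p-values come from a parametric
  bootstrap (default B = 999, seeded): each group redrawn from N(0, S_i)
  with its empirical covariance, p = (1 + #{Q* ≥ Q})/(B + 1). Post hoc:
  the same statistic per variable on every group pair, Bonferroni-corrected
  across (pair, variable). Variables that duplicate others (M2–M4 vs M1)
  are excluded via the `exclude` argument. The shape arm tests at
  α = 0.01 (large object counts), the particle arm at α = 0.05.
* **Mixed-design ANOVA** (between: group; within: neighbor rank k) via
  pingouin, sphericity correction off by default (Greenhouse–Geisser
  available); per-k pairwise Welch t-tests with Benjamini–Hochberg
  adjustment. Subjects missing within-levels are dropped with a warning;
  the pipeline balances the design by using the largest k available to at
  least 80% of synapses.
* **Rank-sum**: exact for small tie-free samples, otherwise normal
  approximation with midrank tie correction and no continuity correction
  (identical samples give p = 1).
* **Adjustment**: Bonferroni and Benjamini–Hochberg step-up, capped at 1,
  monotone.

Type-I error of MATS and rank-sum is verified at 0.05 ± 0.02 over 1,000
null simulations in the test suite.

## The synthetic generator

What it emulates, per data kind:

* **Profiles**: two Gaussian peaks (sd 30 nm) on a constant baseline with
  additive Gaussian noise (default sd 2% of amplitude), sampled every 10 nm.
  Defaults use the 536.7 nm batch-mean separation; the second batch mean
  (510.4 nm) is exercised in tests. Real profiles have structured
  background and asymmetric peaks; the generator does not model those, so
  recovery tests certify the estimator, not robustness to every lab
  artifact.
* **Scaffolds**: six template classes along a morphology continuum — small
  spheres (straddling the 200-voxel threshold), large spheres, ellipsoids,
  two- and three-lobed shapes, and large flat scaffolds with a central
  perforation — built by constructive solid geometry in physical nm
  coordinates and sampled at the anisotropic grid with voxel centers at
  (index + 0.5) × voxel size. Placement is sequential with voxel-exact
  non-overlap (a 26-neighborhood shell is also kept free so segmentation
  cannot merge objects); exceeding the retry budget raises a placement
  error. Object voxels get probability ~N(0.92, 0.04), background
  ~N(0.05, 0.03), both clipped to [0, 1]; the raw-noise statistics of real
  classifier output are unknown, so this Gaussian choice is an assumption
  recorded in the config. A configurable fraction of objects is centered
  near a face to exercise border exclusion.
* **Mosaics**: point patterns in an elliptical ROI — CSR, Thomas-clustered
  (parents CSR, children Gaussian), or hard-core (dart throwing) — rendered
  as isotropic Gaussian spots (sd 2 px: small relative to the spot spacing
  but comfortably resolvable at 25 nm pixels) with axially weighted slices,
  Poisson noise (gain 1) and optional Gaussian read noise. Channel 2 is
  independent CSR or paired to channel 1 at a fixed offset (default 50 nm)
  for a configurable fraction of points. Truth tables carry every
  coordinate and pairing; particle-support masks (disks of 2 px around
  truth points) feed the overlap-distance recovery tests.
* **Planted feature clusters** (`gen_feature_clusters`): 3,000 nine-feature
  vectors from six unit-SD multivariate-normal clusters whose centroids
  span a 3-dimensional subspace of feature space (features covary, as real
  shape features do, so PC1–3 capture the structure) and form three pairs
  at distinct mutual scales — a multi-level hierarchy like the observed
  shape continuum. All pairwise centroid separations are ≥ 8.66 SD
  (parameter `separation_sd`; anything ≥ 6 is "well separated" here). The
  hierarchical arrangement matters: with geometrically symmetric layouts
  (e.g., octahedral centroids) the gap curve can dip at intermediate k and
  firstSEmax stops early even though the clusters are perfectly separated.

Problem sizes in the shipped tests and pipeline defaults (e.g., 25–60
objects per condition, 4–16 synapses, B = 199 bootstrap in the demo run)
are chosen so a full validation runs in minutes on one CPU; all counts are
config fields and scale up without code changes.

## Known limitations

* The pipeline starts from probability maps; pixel-classifier training and
  deformable registration are upstream concerns (the rigid
  maximum-correlation alignment is a deliberate stand-in).
* The isotropic edge correction is evaluated by angular sampling (exact in
  the limit of the angle grid); at 180 angles the bias is far below the
  Monte-Carlo noise of any pattern analyzed here.
* The principal curve is a single non-branching curve; no branching
  trajectory inference.
* Surface areas and sphericity depend on the meshing convention; the
  Gaussian-field marching-cubes choice is documented above and validated
  against closed forms on balls and ellipsoids only.
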