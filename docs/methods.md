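# Methods notes

This note records the models, parameter defaults, numerical choices and
known limitations behind `rsnparc`, in the order the pipeline runs.

## Synthetic cohorts

**Head phantom.** Tissue priors come from a concentric ellipsoidal
phantom: a central CSF "ventricle" (normalized radius r <= 0.18), a WM
core (0.18 < r <= 0.58), a GM shell (0.58 < r <= 0.90) and a thin CSF rim
(0.90 < r <= 1), blurred with a 0.6-voxel Gaussian and renormalized so the
three probabilities never sum above 1. This reproduces the one property
the pipeline actually keys on — GM, WM and CSF occupy distinct, partially
overlapping spatial compartments — and nothing else about anatomy.

**Functional cohorts.** Each planted network is the union of three
Gaussian foci (sigma = 1.6 voxels) centered on strong-GM voxels, masked to
GM and peak-normalized; candidate maps are rejected until all pairwise
spatial correlations are below 0.2, so spatial independence holds by
construction. Networks are multi-focus because resting-state networks are
distributed region sets, and because a single small blob carries almost no
correlation with the whole GM prior, which would make the tissue-based
selection criterion uninformative. Network time courses are unit-SD
Gaussian series band-limited to 0.01–0.08 Hz with in-band power falling as
1/f (pink): spontaneous fluctuations are low-frequency dominated, and this
keeps the expected 0.01–0.05 Hz power fraction near 0.77 rather than
hovering at the 0.5 decision boundary. Subject data are
`sum_k a_sk tc_sk(t) map_k(v) + noise`; the group effect is a
multiplicative amplitude factor (default 1.5) on designated networks in
the patient group, so Z-scored maps genuinely differ between groups.
`noise_sd` is expressed in units of the peak-voxel signal SD of a
unit-amplitude network (time courses have SD 1, maps peak at 1). Optional
confound components — a CSF-shaped map with an in-band time course, and
GM maps with 0.12–0.16 Hz time courses — exercise both rejection rules of
the selection step. Default desk-scale conditions: 20 x 24 x 18 voxels of
3 x 3 x 4 mm, TR = 3 s, 100 volumes, 6–13 subjects per group; the
full-size 53 x 63 x 35 / 200-volume geometry is supported but not default.

**Profile cohorts.** Seed-by-region connectivity counts are Poisson draws
around cluster archetype rates: a shared baseline (1.5 expected counts per
region) plus `separation x 8` extra expected counts on each cluster's
three private support regions. `separation = 1` is the reference
condition; at 0 all archetypes coincide and the data carry no cluster
structure. The two groups may differ in their planted cluster number
(e.g. 4 vs 2), emulating a group difference in parcellation granularity.
Counts are integer and nonnegative by construction; seeds carry true
labels for recovery scoring.

**Toy tracker.** Streamlines start at seed-voxel centers, advance a fixed
step along the local orientation perturbed by small-angle Gaussian noise
(`tan(angle_sd)` times a standard normal added to the unit direction, then
renormalized — accurate for the defaults of ~10 degrees), and stop on
leaving the volume or exceeding a maximum length. Each streamline counts
once per voxel it enters, so per-voxel counts are binomial in the number
of samples. Visitation volumes can be sum-pooled to a coarser grid before
regional aggregation, mirroring tractography outputs saved at reduced
resolution. The tracker is a study device for the aggregation/clustering
chain, not a diffusion model: there is no fiber crossing, no bending
penalty, no probabilistic orientation distribution.

## Preprocessing

Band-pass filtering is an exact orthogonal projection: linear detrend,
FFT-domain mask over [0.01, 0.08] Hz (DC always zeroed), then removal of
the in-band leak of the linear-trend basis. That last step makes the
composite operator the projection onto (band-limited ∩ trend-free), hence
exactly idempotent — detrending and masking alone are projections onto
non-orthogonal subspaces and their composition is not. A half-cosine
roll-off of configurable relative width is available (`transition > 0`)
for users who prefer soft edges; the default width is 0 because any
nonzero taper reattenuates taper-bin content on reapplication. The mask
trivially attenuates everything one octave beyond the band edges by more
than 20 dB.

Smoothing converts FWHM to per-axis sigma via voxel size
(sigma = FWHM / (2 sqrt(2 ln 2))) and convolves each volume with
zero-padding and no boundary renormalization, following the convention of
the standard SPM ecosystem; constant-preservation invariants therefore
hold for interior voxels only.

Flattening uses a fixed x-fastest raster (NIfTI convention): column `i`
is voxel `(i % nx, (i//nx) % ny, i//(nx*ny))`. All cross-comparisons of
maps must use the same raster (the generators' 3D truth maps are
flattened with the same helper).

## Group ICA

Per-subject PCA keeps the top C = K singular directions (the reference
full-size analysis uses K = 40, matching M = 26 x 40 = 1040; desk-scale
runs default to K = 2 x the expected network count, e.g. 12 for 6 planted
networks — over-specifying K further is harmless for group maps but
dilutes back-reconstructed subject maps, see below). The concatenated
matrix is row-centered and whitened to K dimensions inside Infomax.

Infomax hyperparameters (unstated in the reference methodology; fixed
here for reproducibility): learning rate 0.01/ln(K+2), block size
max(8, sqrt(N/3)), max 512 passes, convergence when the relative weight
change per pass drops below 1e-6. The learning rate halves on numerical
blow-up, decays by 0.9 whenever the per-pass update stops shrinking, and
decays by 0.985 per pass after a 64-pass burn-in so the stochastic
updates settle below tolerance. Non-convergence is reported as a warning
plus a `converged` flag, never an exception. The ICA sign ambiguity is
canonicalized by flipping each component so its spatial skewness is
nonnegative (applying the rule twice is the identity); maps are scaled to
unit variance with the inverse scale absorbed into the mixing matrix.

Back-reconstruction partitions the mixing matrix into consecutive
per-subject C x K blocks A_i: subject time courses are `bases_i @ A_i`,
subject maps `pinv(A_i) @ reduced_i`. With one subject this reduces to
ordinary ICA. Subject-map fidelity is high at the true model order (all
subject-vs-group map correlations > 0.98 on the default cohort at K = 6)
and degrades when K far exceeds the true source count, because the extra
noise components contaminate the per-subject inversion — a real property
of this reconstruction scheme, reproduced rather than hidden here.

## Stability (ICASSO-style)

Infomax is rerun `n_runs` times (default 10; 5 in the timed acceptance
run) with different update orders; runs after the first resample the rows
(time points) of the concatenated matrix with replacement. The resampling
unit is a package choice — the reference procedure does not state one —
and row bootstrap was chosen for simplicity. Pooled components are
clustered by average-linkage agglomeration on 1 − |spatial r| into K
clusters (K equal to the component count). The stability index of a
cluster is its mean intra-cluster similarity (self-pairs included) minus
its mean similarity to out-of-cluster components. The index is bounded in
[−1, 1] and is invariant to sign flips and run order; for identical runs
it approaches but does not exactly equal 1, because distinct ICA
components are decorrelated only approximately, leaving a small positive
extra-cluster term. Each cluster is summarized by its centrotype (member
with maximal within-cluster similarity sum).

## Component selection

A component is kept iff (i) its GM correlation is at least 0.15 and
exceeds both its WM and CSF correlations, and (ii) its time course holds
at least 50% of its DC-excluded periodogram power within 0.01–0.05 Hz
(with several subjects, power fractions are averaged). The 50% rule and
the 0.01–0.05 Hz window are fixed by the method being implemented; the
tissue thresholds are not stated there, so the default is a rank-based
rule (reject when WM or CSF beats GM) plus a low absolute GM floor —
rank rules are robust to the overall sparsity of component maps, and
absolute WM/CSF ceilings remain available as parameters. Correlations are
computed over in-brain voxels (summed tissue probability > 0.1). Matching
of kept components to named networks is by correlation against
user-supplied template maps only; no template atlas is bundled.

## Voxelwise group statistics

The within-group analysis mask is the intersection of one-sample
activation maps thresholded at p = 0.001 (one-sided, positive — component
maps are activation-signed). Between-group inference is a per-voxel GLM
with intercept, group indicator and the mean-motion covariate; the group
contrast t has n − 3 degrees of freedom. A constant covariate is dropped
(df n − 2) since it carries no information; a covariate collinear with
the group indicator raises an error. Cluster-forming uses the two-sided
threshold |t| > t_{1−p/2}; positive and negative excursions are labelled
separately (6-face connectivity by default, configurable) so
opposite-signed effects cannot merge into one cluster. Family-wise error
is controlled by permutation: group labels are shuffled, the covariate
refit, and the maximum suprathreshold cluster extent recorded per
permutation; a cluster is significant iff extent >= k_min (default 5) and
its permutation p is below 0.05. Permutation max-statistic correction
replaces random-field theory deliberately: at desk scale and with
synthetic smoothness, RFT's assumptions are not defensible, while the
permutation test is exact under exchangeability and directly testable
(the null family-wise false-positive rate is checked in the acceptance
suite). Clinical correlations are computed voxelwise inside a 10-mm
sphere around an a-priori peak; the in-sphere peak correlation is
Bonferroni-corrected by the number of in-sphere voxels (the small-volume
correction); with radius 0 the test is the single peak voxel,
uncorrected. Pearson is the default for map-score regression and Spearman
for scalar-scalar correlations, mirroring the mixed usage of the
reference analysis.

## Parcellation

Seed extraction applies the 2D Sobel operator slice-by-slice (axial) to
the non-binarized GM probability, keeps voxels whose gradient magnitude
reaches 25% of the slice maximum (the reference procedure states no
threshold; 25% is configurable), intersects with the region probability
map at >= 50%, and removes seeds any of whose six face neighbors has CSF
probability above 0.5 — an automated, reproducible version of manual
CSF-facing seed removal.

Profiles are row-L1-normalized before clustering (the reference pipeline
states neither normalization nor metric; L1 removes seed-depth count
biases and makes cluster selection invariant to global count scaling;
raw counts and other metrics remain available). k-means uses k-means++
initialization with 20 restarts (10 in timed runs) and a fixed seed; the
silhouette sweep covers k = 2..15 inclusive, groups are processed
separately, and ties in the argmax break toward smaller k (parsimony).
When the best mean silhouette falls below 0.25 the result is flagged
"no structure" and no k is chosen; Poisson sampling noise around
identical archetypes stays well below this floor while the reference
separation sits well above it. The silhouette is the canonical
Rousseeuw dissimilarity form s(i) = (b − a)/max(a, b); the
similarity-ratio reading of the procedure's prose is available as
`variant="similarity_ratio"` (similarity kernel 1/(1+d), per-seed ratio
of mean within-cluster similarity to the maximal other-cluster mean,
mapped to [−1, 1] by (ratio−1)/(ratio+1)) — the canonical form is the
default because the procedure cites the canonical references.

Cluster centroids are matched across groups by Hungarian assignment on
centroid correlation; with unequal k the unmatched clusters are reported
as group-unique. Within matched pairs each region is classified by a
peak-presence threshold (0.05 of normalized profile mass) and a relative
change threshold (30%) into present-in-one-group / increased / decreased /
unchanged / absent; the report is symmetric under swapping the groups.
Per-subject seed counts per cluster are compared by Welch t tests and
correlated with clinical scores by Spearman rank correlation; subjects
with no seeds in a cluster count 0, not missing.

## Problem sizes and determinism

Default test and acceptance problem sizes are desk-scale by design — a
20 x 24 x 18 x 100 cohort of 12 subjects for ICA recovery, 9 x 9 x 7
nulls with 1000 permutations for FWE calibration, 120-seed profile
matrices for the silhouette sweep — chosen so the full suite and the
acceptance script each complete in about a minute while leaving every
statistical check adequately powered. All generators and estimators take
explicit seeds; identical seeds give bit-identical outputs.

## Known limitations

- No hemodynamic response model, MR physics, or realistic anatomy: the
  generators emulate the statistical structure the pipeline consumes
  (spatial independence, band-limited coherence, tissue compartments,
  Poisson count profiles), not the physiology that produces it. Passing
  tests demonstrate correctness and calibration of the pipeline, not
  performance on real data.
- The toy tracker is not probabilistic tractography; visitation counts
  from it share only the count statistics and geometry of the real thing.
- GICA1-style back-reconstruction is used (no two-stage group PCA, no
  dual regression); its subject maps degrade at inflated model order.
- Silhouette-based model selection inherits k-means' bias toward
  spherical clusters in the normalized profile space.
- Permutation FWE assumes exchangeability of subjects under the null
  (satisfied by the generators; approximately true for real cohorts after
  covariate adjustment).
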