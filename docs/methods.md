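# Methods

This note documents the models, algorithms, parameter defaults, and design
choices behind `dualtrace`, and what the synthetic fixtures do and do not
establish about real imaging data.

## Imaging geometry and containers

All stacks are (z, y, x) intensity grids with a physical voxel size,
defaulting to 1.08 × 1.08 µm laterally and a 3 µm z step — a typical 20×
confocal tiling geometry for coronal sections, with three optical planes
spanning a 9 µm imaged thickness. A segmented object is a connected set of
voxels with a centroid in µm, a voxel count, volume (voxel count × voxel
volume), and peak intensity. Data are organized hierarchically: slice
records (imaging metadata, imported objects, registration, per-hemisphere
exclusion annotations) nest inside mouse records, which nest inside an
experiment holding at most two groups.

## Segmentation

Two algorithms match the two staining morphologies of dual-ensemble
experiments.

**Punctate (nuclear) labels.** Stages in order: (1) lateral band-pass
implemented as a per-plane difference of Gaussians with a 2–20 voxel pass
band (the Fourier band-pass of batch-processing macros is equivalent up to
window shape); (2) rolling-ball background subtraction, implemented as a
per-z-plane grayscale opening with a disk of radius 15 voxels subtracted
from the image — the per-plane convention matches how slide scanners and
batch macros treat anisotropic stacks, where a 3D ball of 15 lateral voxels
would span only ~5 z-planes and behave differently; (3) 3D local-maxima
seeding over an anisotropy-corrected ellipsoidal neighborhood (4 lateral
voxels); (4) spot growth: marker-based watershed basins around the seeds,
with each basin cut at 50% of its seed intensity and reduced to the
connected piece containing the seed — touching cells stay split along the
watershed line; (5) volume filtering (30–∞ voxels by default).

Seeds must clear two thresholds: median + 5 robust SDs of the filtered
stack (MAD × 1.4826), and 20% of the maximum filtered response. The second
floor exists because on nearly noise-free images the MAD collapses and
filter ringing would otherwise seed spurious objects; on noisy images the
first threshold dominates. Both are parameters.

**Somatic labels with processes.** Stages in order: rolling-ball background
subtraction; 3D Gaussian blur (σ = 2 lateral voxels, z scaled by the voxel
anisotropy); a binary mask of the 0.5% brightest voxels; marker-based
watershed of the mask seeded at blurred-intensity maxima; volume filtering.
Processes are suppressed because a thin filament's blurred intensity falls
below the global top-percentile cutoff. The top-percent threshold selects
the largest floor(n × p/100) voxels using an order-statistic cutoff with a
strict comparison: a constant image yields an empty mask and the selected
fraction can never exceed p/100 (an interpolated percentile can overshoot
that bound by one voxel on non-tied data, which is why the order statistic
is used). The soma minimum object volume defaults to 15 voxels, lower than
the punctate default: the global percentile budget leaves dim cells (e.g.
on the dark side of an illumination gradient) only a small bright core, and
the mask is empirically free of sub-soma debris because filaments are
already excluded by the cutoff.

Manual deletion of autofluorescence artifacts at tissue edges is replaced
by an optional edge-margin parameter that drops objects whose centroids lie
within a configurable number of lateral voxels of the border; there is no
interactive editing.

Object labeling and watershed use 26-connectivity throughout.

**Colocalization.** Candidate co-labels are enumerated directly from the
two channels' label volumes: one record per ordered object pair sharing at
least one voxel, with percent overlap measured relative to the channel-2
object's volume. Thresholding keeps records at or above a minimum percent;
a channel-2 object surviving in several records counts as one co-labeled
cell, assigned to its largest overlap (ties to the lower channel-1 id).
The numeric threshold is a required configuration value — there is no
universal default, since it trades precision against recall of the overlap
population.

**Validation arithmetic.** Against manual counts, the true-positive total
is estimated as the mean of two derivations, (manual − FN) and
(auto − FP); precision = TP/(TP+FP), recall = TP/(TP+FN), and F1 is their
harmonic mean, 1/F1 = (1/P + 1/R)/2.

## Registration and mapping

Registration is a 2D thin-plate spline fitted from correspondence points
(32 by convention for contour seeding) with kernel U(r) = r² log r and an
affine part, solved with the standard side conditions. λ = 0 interpolates
every control point exactly (the default, matching interactive
point-correction workflows where the corrected points are trusted); λ > 0
trades exactness for smoothness with noisy points. Three non-collinear
points reduce exactly to the unique affine map. Collinear or duplicated
points raise a singular-system error.

Image pixels are x-right/y-down; atlas coordinates are µm, x-right/y-up
with the midline at x = 0 (hemisphere is the sign of atlas x). The
transform absorbs the flip. Registration along the rostro-caudal axis is
plate snapping only — a slice is manually matched to its best
anterior–posterior plate, mirroring the ~100 µm plate spacing that limits
z resolution in section-based registration.

Warped cell centroids are assigned to plate regions by an even-odd
point-in-polygon test; boundary points go to the first-listed polygon, and
points in no polygon are unassigned and dropped from tallies. Region areas
use the shoelace formula (orientation-independent); a region's volume per
mouse is its summed per-slice area × section thickness, and densities are
counts/volume in cells/mm³.

Exclusions: annotated (acronym, hemisphere) pairs propagate to all
descendants of the acronym in the region ontology — excluding a parent
without its children would silently bias aggregate counts. Fiber tracts and
ventricular structures are always excluded. Unknown acronyms raise with
nearest-match suggestions to catch misspellings. Zero-volume imported
objects are dropped with a warning rather than erroring, tolerating
upstream export artifacts; a region with counts but zero mapped volume is
an integrity error.

**Quality checks.** Outlier cleaning drops rows whose density lies more
than k = 2 sample SDs (n − 1) from the (group, region, channel) mean, in a
single pass with the candidate row included in the statistics — no
iteration, so the rule is idempotent. An all-equal group removes nothing.
Only (region, channel) pairs represented in both groups are analyzed;
"represented" defaults to a retained row for every mouse, with a
configurable relaxation to ≥ m mice per group. Reactivation proportions
divide co-labeled counts by a reference channel's counts per region and
mouse; the ratio is computed on counts, which is volume-invariant since
both channels share the mapped volume.

## Network statistics

Correlations are pairwise-complete Pearson coefficients of per-mouse
densities, with the per-pair n recorded; pairs with n < 3 or a constant
region are reported missing. Two-sided p-values use the one-sample t
transform t = r√(n−2)/√(1−r²) on n−2 degrees of freedom, with |r| = 1
mapping to p = 0.

Networks keep edges with |r| > r_min (default 0.9) and p < α. The absolute
value is used because anti-correlations are as informative as correlations
for co-activation structure; a signed option exists. α is a required
configuration value per channel — edge sparsity is a judgment call (0.01
and 0.005 are typical), and no principled default exists.

Topology metrics are computed on the unweighted, sign-ignored skeleton
(the signed r is carried on edges for presentation only): degree;
clustering 2T/(d(d−1)) with 0 for d < 2; nodal efficiency as the mean
inverse shortest-path length to all other nodes (1/∞ = 0 for unreachable
pairs), whose network mean is the global efficiency; betweenness
unnormalized with each unordered pair counted once (normalization is an
option). Threshold sweeps recompute the network means across a sorted
α grid to check that group comparisons are not artifacts of one threshold.

The permutation test subtracts the two groups' correlation matrices
(d = r_B − r_A per pair) and compares each observed d to a null built by
shuffling group labels over the pooled mice (group sizes preserved; 1000
shuffles by default). P-values are two-sided on |d| with the add-one
estimator (#{|d_null| ≥ |d_obs|} + 1)/(N + 1), which is never zero and is
exact under exchangeability. No multiple-testing correction is applied by
default: the analysis is exploratory and deliberately tolerates false
positives over false negatives. A region's correlation distribution is
compared between groups with a two-sample Kolmogorov–Smirnov test on its
off-diagonal r values.

Community detection is the one-level spectral split: B = A − k kᵀ/(2m) on
the unweighted skeleton, vertices separated by the sign of the eigenvector
of the largest positive eigenvalue, with a single community returned when
that eigenvalue is not positive. **Known limitation:** the one-level sign
split recovers well-separated modules (disconnected cliques, barbells,
two-block structures) exactly, but it is not guaranteed to attain the
maximum-modularity 2-partition on arbitrary graphs — on unstructured or
highly symmetric graphs (e.g. even cycles with degenerate leading
eigenspaces) it can land on a suboptimal split. No refinement pass is
applied, keeping the method exactly as stated.

## Synthetic fixtures

**Phantoms.** Cells are Gaussian-profile spheres (σ = radius/2, default
radius 6 µm) placed by rejection sampling with centers at least 2 radii
apart, on a constant background (default 100) modulated by a multiplicative
low-frequency illumination gradient (one lateral period, default amplitude
20%) with additive Gaussian noise; SNR is the cell amplitude over the noise
SD (default 10, amplitude 200). The soma morphology adds random-walk
filaments from the soma surface (3 per cell, 40 µm, persistent 2 µm steps)
whose peak intensity is 40% of the soma amplitude, max-combined so
crossings do not brighten. Dual-channel phantoms place a designed fraction
of channel-2 cells on channel-1 centers (within an optional jitter), with
the designed overlap fraction recorded analytically from the equal-sphere
intersection volume. Default grid 16 × 128 × 128 voxels.

What phantoms do not emulate: realistic point-spread functions, chromatic
offsets between channels, autofluorescent structures, staining gradients
with tissue depth, cell-to-cell brightness variation beyond the
illumination gradient, and densely packed layers (minimum separation is
enforced). Passing the recovery suite therefore demonstrates correctness of
the algorithmic chain at genuinely favorable contrast, not performance on
adversarial tissue.

**Count simulation.** Counts are lognormal-then-rounded (mean 500,
log-scale SD 0.3 — positive, right-skewed, mildly dispersed, in the range
of per-region densities after normalization), with cross-region dependence
from a Gaussian copula so a planted latent correlation survives the
marginal transform nearly unchanged at this dispersion (analytic
attenuation < 0.01 at r = 0.95). Pairs planted at exactly r = 1 share one
latent draw and correlate exactly. Target matrices are repaired to the
nearest correlation matrix by clipping eigenvalues below 1e-8 and
renormalizing the diagonal; a repair that moves any entry by more than 0.1
is rejected as unsatisfiable. Group sizes default to 8 mice — a realistic
cohort for section-based mapping studies.

**Toy atlas.** Plates are lists of labeled, non-overlapping simple
polygons with an ontology subtree; the 2 × 2 unit-square grid gives exact
expected areas and assignment probabilities for tests.

## Problem sizes and numerical choices

The verification suite uses: 10 phantom seeds per algorithm (20 punctate /
15 soma cells each) for segmentation recovery; all 143 connected graphs on
≤ 6 nodes against an exhaustive path-enumeration oracle for the topology
metrics; a 39 × 7 (r, n) grid against numeric integration of the t density
for correlation p-values; 500 replicate null datasets (8 mice/group, 20
regions, 200 shuffles) for permutation calibration, expecting a rejection
rate near the 0.0498 attainable at that shuffle resolution; 200 replicates
(12 mice/group) of a +0.9/−0.9 planted flip for power; and a structured
family of 13 modular graphs (≤ 8 nodes) against brute-force enumeration of
all 2-partitions for community detection. TPS exactness is asserted to
1e-8 at control points; degenerate TPS systems are detected by rank (tol
1e-9 scaled) and explicit duplicate checks. All generators take explicit
seeds and are bit-reproducible; `scripts/acceptance.py` derives every seed
from its `--seed` argument.
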