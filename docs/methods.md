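# Methods

This note documents the models, parameter choices and numerical decisions
behind `stisodata`, and what the synthetic phantom does and does not
emulate.

## Pipeline overview

The pipeline runs, in order: CSF/vessel exclusion → relative-map computation
→ spatial contiguity weighting → feature assembly → ISODATA clustering →
CoV pruning → 1–100 normalization → signature binning → temporal profiles →
tissue classification → Dice evaluation. Inputs are assumed co-registered
and skull-stripped; registration, brain extraction and diffusion-tensor
fitting are out of scope (the phantom is born aligned).

## Preprocessing

**CSF/vessel exclusion.** Voxels with first-timepoint ADC strictly greater
than 1.2x10^-3 mm^2/s are removed from the analysis mask. The comparison is
strict: a voxel exactly at the threshold is retained.

**Relative maps.** Each map is divided by its mean over the *contralateral
hemisphere inside the analysis mask*, so the excluded CSF/vessel voxels do
not inflate the normalizer. (Whether to average over the whole hemisphere or
the masked hemisphere was an open choice; the masked variant is more robust
to ventricle size.) The relative parameter kind (rADC/rFA/rT2) is tracked
and re-normalizing an already-relative map is refused rather than silently
repeated.

**Spatial contiguity weighting.** Each in-mask voxel of each relative map is
replaced by the weighted mean of its in-mask 3x3x3 neighbourhood, with
Gaussian distance weights w(d) = exp(-d^2 / (2·decay^2)), decay = 1.0 voxel,
out-of-mask neighbours excluded and weights renormalized to sum to one. The
centre voxel always participates, so isolated voxels keep their value. This
is the concrete realization of a local-homogeneity constraint that suppresses
voxel-level noise before clustering; radius and decay are configurable.

**Features.** One row per analysis-mask voxel; columns are (timepoint,
parameter) pairs in timepoint-major order — 7 timepoints x 3 parameters = 21
columns for the full combination. Columns are z-scored by default (the
(mean, sd) pairs are recorded on the model), which makes parameters with
different dynamic ranges commensurate under a diagonal Mahalanobis metric.

**Temporal profiles** are read from the *unsmoothed* relative maps. The
contiguity weighting exists only to stabilize clustering; at lesion borders
it mixes lesion and normal values and would bias per-signature means.

## ISODATA

**Covariance.** All Mahalanobis computations share one global diagonal
covariance estimated from every analysis-mask row (essentially the identity
after z-scoring), regularized by adding 1e-6 x mean(diagonal). A single
global metric keeps centroid-to-centroid distances (D_inter) symmetric and
well defined; per-cluster covariances would make them asymmetric.

**Parameters.** Defaults: Φ_N = 100 voxels, k = 6 initial clusters, K = 8,
I = 100 iterations, ε_r = 1e-4, L = 1 merge per iteration. The allowed
cluster-count range "(0.5 K, 2 K + 1)" is read with K the configured anchor:
integers 5…16 for K = 8. Φ_C and Φ_S are derived from the data: Φ_C as the
Mahalanobis distance between the contralateral WM and GM mean feature
vectors, Φ_S as the pooled *population* standard deviation of WM feature
values over rows and columns. Note the unit tension inherited from the
procedure: Φ_S is a scalar value spread while D_intra is a distance in the
t·f-dimensional feature space; z-scoring the features keeps the two on
comparable scales, but D_intra of even a pure-noise cluster grows with the
feature dimension, so Φ_S effectively controls *relative* dispersion, not an
absolute one.

**Initialization** is semi-randomized and distance-proportional: the first
centroid is a uniformly random row; each next centroid is the row at which
the cumulative summed distance to the already-chosen centroids first exceeds
a uniform random fraction of the grand total. Distances here are Euclidean
in the feature space as given — deliberately *not* whitened by the global
covariance, which absorbs between-cluster spread and would flatten exactly
the contrast the seeding relies on. Already-chosen rows are excluded from
re-selection.

**Iteration.** Assign (ties to the lowest cluster id) → recompute centroids
→ discard clusters below Φ_N (their voxels move to the nearest surviving
centroid; an all-small configuration is a hard error) → split or merge →
recompute → convergence check. Splitting and merging alternate by iteration
parity (split on odd, merge on even); only the single worst offender
(largest D_intra above Φ_S) is split per iteration, into children at
µ ± 0.5·σ_max along the axis of largest per-column sd, skipped if either
child would fall below Φ_N or the count would leave the allowed range. If
discarding pushes the count below the range's lower bound, a split is forced
regardless of parity and of Φ_S. Merging joins the closest pair with
D_inter < Φ_C (size-weighted mean centroid), at most L pairs per iteration,
never below the lower bound.

**Stopping.** Convergence error is the maximum over clusters of
‖µ_new − µ_old‖ / (‖µ_old‖ + 1e-12) across one iteration; below ε_r the loop
stops. The split and merge rules can also undo each other indefinitely: a
split whose children sit closer than Φ_C is merged straight back, giving a
2-cycle the displacement criterion never exits. The loop therefore hashes
each iteration's partition and, on recurrence, stops at the cycle state with
the fewest clusters — the state in which every surviving pair separation is
maximal. Reaching I iterations without either stop is logged, not an error.
All randomness flows through one seeded generator; the seed is recorded on
the model and identical seeds give bit-identical assignments.

## Pruning, normalization, binning

**CoV pruning.** A cluster's temporal coefficient of variation is computed
per parameter on its centroid trajectory *in relative units* (de-z-scored),
as population sd over timepoints divided by the mean; the pooled CoV is the
maximum over parameters — a cluster dynamic in any one parameter is
abnormal. Clusters with pooled CoV ≤ 0.05 (default) merge into a single
normal cluster with size-weighted centroid. Voxel counts are conserved.

**Normalization.** Because high-ADC voxels are excluded before clustering,
no CSF cluster exists; the CSF and WM anchors are instead reference feature
vectors computed directly from the CSF and contralateral-WM ROIs on the
(unsmoothed) relative maps. Each cluster's raw position is
s = ‖µ − wm‖ / (‖µ − wm‖ + ‖µ − csf‖) under the model metric — monotone in
relative proximity to CSF — affinely rescaled over clusters so the
WM-nearest cluster lands exactly at 1 and the CSF-nearest at 100. The
mapping is invariant to joint affine rescaling of centroids and anchors.

**Binning.** Values ≤ 5 are Signature N; then closed tens ranges: 6–15 → I,
16–25 → B2, 26–35 → II, 36–45 → III, 46–55 → IV, 56–65 → V, 66–75 → B7,
76–85 → B8, 86–95 → B9, 96–100 → B10. The B-bins are generic labels for
ranges with no named signature. The boundary between "below 5" and the
"1–5" range is resolved as v ≤ 5 → N.

## Tissue classes and evaluation

Lesion ROIs (acute 1-h ADC lesion, maximal T2 lesion, chronic T2 lesion) are
enlarged by three binary dilation steps with the 6-connected (face-adjacent)
element — the most conservative 3D growth; 26-connectivity is available via
config — then clipped to the brain mask. Classes follow set identities:
Core = acute ∩ chronic, Growth = chronic \ acute, Recovery = acute \ chronic,
Edema = maximal \ (acute ∪ chronic); acute membership takes precedence, so a
voxel in maximal ∩ acute \ chronic is Recovery, not Edema. All three ROIs
are dilated uniformly before classification.

**Dice.** Counts are taken within the ipsilateral analysis mask (signature
analysis is restricted to the ipsilateral parenchyma; the evaluation region
follows for consistency). Two empty masks score DSI = 1 (logged when it
happens); an empty reference against a nonempty prediction scores 0.

**Sweep.** Six input combinations x ten CoV thresholds (0.10 → 0.01, step
0.01). Clustering does not depend on the CoV threshold, so each combination
is clustered once and pruned at every threshold; the result is identical to
running each configuration independently. Each (dataset, combination) run
gets a seed derived from the master seed and a hash of the configuration
name, stable under grid reordering. Per-configuration failures are recorded
and the sweep continues.

## The synthetic phantom

**What it emulates.** An ellipsoidal brain split at the mid-sagittal plane
(left = ipsilateral by convention; 0-based voxel indices, axis order
(x, y, z)), a grey-matter shell over a white-matter interior and a central
CSF compartment, with physiologically typical baselines (WM: ADC
0.70x10^-3 mm^2/s, FA 0.45, T2 80 ms; GM: 0.80x10^-3, 0.15, 95 ms; CSF:
3.0x10^-3, 0.05, 2000 ms — CSF deliberately above the ADC exclusion
threshold). Ellipsoidal lesion regions planted in the ipsilateral hemisphere
follow per-signature relative time-courses; the default anchor tables
realize the qualitative orderings that distinguish the signatures (deepest
acute rADC drop for V, then II; a sharp first-day rADC rebound for IV;
acutely depressed rFA only for V; monotone rT2 rise for II and V; the
fastest post-3-h rT2 rise for IV bar V), interpolated piecewise-linearly in
log-time between the seven default timepoints (1, 2, 3, 24, 72, 144, 240 h).
Additive Gaussian noise is independent per voxel/timepoint/parameter with
default sd 5% of the WM baseline (ADC 0.035x10^-3, FA 0.0225, T2 4.0); FA is
clipped to [0, 1], ADC/T2 at 0.

**Lesion anchoring.** Lesion-voxel noiseless values are (contralateral
analysis-mask mean of the parameter) x (profile multiplier), not (local
compartment baseline) x multiplier. The profiles are *relative*
time-courses, and this anchoring guarantees that contralateral normalization
recovers the configured multipliers exactly on a noiseless phantom,
independent of the WM/GM mix of the normal hemisphere. The package treats
this as part of the phantom's definition.

**Ground truth.** Truth ROIs come from the noiseless relative maps: acute =
voxels with 1-h rADC < 0.85; chronic = final-timepoint rT2 > 1.25; maximal =
the abnormal extent (either criterion) at the timepoint where it is largest.
The thresholds separate normal-tissue relative values (WM ≈ 0.95–1.0 rADC,
GM ≈ 1.15 rT2) from every planted profile. Truth classes follow from the
ROIs by the set identities above; `generative_labels` additionally codes the
normal compartments, giving the exact generating partition that clustering
is scored against.

**What it does not emulate.** No acquisition or k-space simulation, no
motion, registration error, bias fields, partial-volume mixtures beyond
what the contiguity smoothing induces, no anatomically realistic cortical
folding, and lesions are uniform within a region (no internal gradients
except at borders). Passing tests on the phantom therefore demonstrate
correctness of the algorithmic chain and its behaviour under additive noise
— not performance on real macaque or human MRI, where registration residues
and tissue heterogeneity add failure modes the phantom cannot expose.

## Problem sizes and defaults used by the test suite

The default phantom is 64x64x24 voxels (~37k analysis voxels, 21 features),
chosen so the full pipeline and the complete 60-configuration sweep run in
seconds; the unit-test phantom is 32x32x16. The acceptance script uses the
default size end to end.

## Known limitations

- The cluster structure near the Φ_C boundary is seed-sensitive: pairs of
  signatures less mutually separated than contralateral WM vs GM can merge
  when the cluster count sits above the range's lower bound.
- Φ_S derived as a WM value sd is dimensionally unlike D_intra (see above);
  the derivation is kept as specified but relies on z-scored features.
- The lesion-border gradient created by contiguity smoothing typically forms
  its own (abnormal) cluster; it inflates the abnormal region slightly and
  is the main source of false positives in the Dice scores.
- The CoV pruning threshold acts on noiseless-looking centroid trajectories;
  with very few voxels per cluster the centroid CoV itself becomes noisy.
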