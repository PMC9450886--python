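# Methods

This note documents the models, defaults, numerical choices, and known
limitations of `fishclust`, in the spirit of a methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Trace preprocessing and feature extraction

A trace is a strictly time-ordered sequence of ≥2 frames `(t, x, y, z)` in
cm, with depth (`z`) possibly missing per frame (in real recordings the
depth stream occasionally returns no point at the fish, typically <1% of
frames).

1. **Diffraction correction.** Water refracts the stereo-depth signal, so
   in-water `z` is mapped to true depth by a line fitted by ordinary least
   squares to paired calibration measurements of the same points with and
   without water (`z_air ~ z_water`). The regression direction (true depth
   on measured depth) is a package choice; a two-point calibration is exact
   by construction.
2. **Interpolation.** Interior gaps in `z` are linear in time between the
   flanking measurements; gaps at the trace ends take the nearest available
   value (a choice — "interpolation" alone does not define end behavior).
   Present values are never modified.
3. **Smoothing.** Each coordinate channel is Savitzky–Golay filtered,
   window 7 frames, polynomial order 3, with polynomial edge handling so
   output length equals input length. Smoothing feeds bottom distance,
   center distance, and distance travelled; percent explored uses the
   unsmoothed (corrected, interpolated) trace so voxel occupancy reflects
   measured positions. A `smooth_explored` flag flips that choice.

The four features:

- **Bottom distance** `B`: mean unsigned point-plane distance to the bottom
  plane, which is fit to ≥3 non-collinear floor points by regressing `z` on
  `(x, y)` (the floor is near-horizontal, so z-residual least squares is
  appropriate; the unit normal is oriented into the water). Aggregation
  over the trial is the arithmetic mean over frames — a scalar summary must
  be chosen and the mean is the standard one; medians would differ only
  under skew.
- **Center distance** `C`: mean perpendicular distance to the vertical line
  through the tank center (center-top to center-bottom points).
- **Distance travelled** `L`: sum of successive-frame Euclidean step
  lengths. In the binned variant, steps (not frames) are partitioned, so
  per-bin `L` sums exactly to the whole-trial `L`.
- **Percent explored** `E`: `100 ×` (occupied voxels)/(total voxels) on a
  10 × 10 × 10 grid over the full 15 cm tank cube by default, so voxels
  above the waterline exist but are unreachable and `E` for a fish confined
  to the water tops out below 100%. Gridding only the water volume is
  available via `voxel_z_extent`. Voxels are half-open boxes `[lo, hi)`
  with the last box closed; frames outside the grid are clamped to boundary
  voxels with a warning rather than dropped.

Defaults with units: tank side 15 cm; water depth 11.1 cm (2.5 L over a
225 cm² base); frame rate 30 fps; smoothing window 7 frames, order 3;
voxel grid 1000.

## Synthetic data: the stated world

`generate_trace` simulates a bounded correlated random walk: a heading
vector follows an AR(1) process with coefficient `turn_persistence`
(innovation variance scaled by `1 − φ²` for stationarity), blended each
frame with a vertical drift toward `depth_pref` and a horizontal radial
drift of strength `wall_affinity` (positive toward the walls, negative
toward the center line); per-frame speed is truncated-Gaussian
(`speed_mean`, `speed_sd`); walls, floor, and surface reflect. Drift gains
(1.2 vertical, 1.0 radial, in cm/s) were chosen so behavioral biases
dominate the noise without pinning fish to boundaries.

The four archetype parameter sets are calibrated so the *extracted
features* reproduce the canonical cluster profile orderings (shy lowest
`B` and `E`; wall-huggers highest `C`; active explorers highest `L` and
`E`; bold highest `B`, lowest `C`, below-average `L`). Absolute trace
statistics for real fish are not published, so only the orderings, not the
magnitudes, are calibrated — within-archetype variances are package
choices stated in the defaults, not claims about real cohorts.

Cohorts: the default composition mirrors a realistic 426-fish reference
design (AB 58F/52M, TL 54F/50M, TU 58F/50M, WIK 51F/53M). Each fish's
archetype evolves across sessions as a first-order Markov chain: kept with
probability `persistence` (default 0.6), else resampled from its
strain-sex group's archetype probabilities. The closed-form
session-to-session label agreement `p + (1−p)·Σqᵢ²` is verified by
simulation in the tests. `generate_feature_cohort` is a fast path that
draws feature vectors directly from per-archetype Gaussians (pairwise
centroid separation ≥3 within-cluster sd in every discriminating feature)
and skips trace simulation.

**What a green test does and does not establish.** The generator produces
exchangeable Gaussian-ish feature clouds with planted structure; it does
not emulate tracking noise autocorrelation, missing-depth burstiness,
within-trial habituation drift, tank-wall reflections of the depth stream,
or inter-feature correlations beyond those induced by archetype membership.
Recovery results (ARI = 1, ≥95% assignment fidelity) therefore certify the
pipeline's correctness on well-posed input, not its robustness to real
tracking artifacts.

## Clustering

- **Standardization**: z-scores with sample sd (ddof = 1); new data are
  standardized with the *reference* parameters so they live in the fitted
  model's space.
- **Similarity**: `S = 1/(1+D)` on standardized 4-D Euclidean distance `D`
  — bounded in (0, 1], strictly decreasing, `S(0) = 1`. `exp(−D)` is
  available via `form="exp"`. (The exact published functional form is not
  reproducible from the available text; this choice is flagged
  accordingly.)
- **Graph**: union-symmetrized k-NN (edge iff either endpoint ranks the
  other in its top k), guaranteeing minimum degree k; similarity ties break
  toward the lower node index so the edge set is deterministic.
- **Louvain**: `networkx` implementation, resolution 1.0, node-visit order
  seeded; labels renumbered 1..C by descending community size (ties toward
  the community containing the smallest node id) so "cluster 1" is
  reproducible. An independent igraph implementation and, on tiny
  fixtures, brute-force enumeration of all partitions serve as oracles in
  the tests.
- **k selection**: for each scanned k the partition is scored on the
  standardized feature cloud (these indices are defined on point clouds,
  not graphs) with Calinski–Harabasz (↑), Silhouette (↑), Davies–Bouldin
  (↓). A k is a candidate if its mean index rank is in the top `1/window`
  quantile (window = 5); the selected k is the middle of the longest
  contiguous candidate run with constant community count — an
  operationalization of "middle of a regime that optimizes internal
  clustering and is robust to small changes in k". With no run of length
  ≥2 the single best k is returned with a warning.
- **Assignment**: `m = max(⌊n_min/2⌋, 1)` nearest reference fish by
  similarity; majority label; ties resolved by larger total similarity
  among tied communities, then lower community id. (With the reference
  smallest cluster at 82 this yields m = 41; 82/2 is exact so floor vs
  round is unobservable.)
- A practical caveat found during testing: modularity on sparse k-NN
  graphs can subdivide a large, well-separated blob when k is much smaller
  than the cluster size; k of the order of half the smallest expected
  cluster behaves well, which is also where the index plateau lands.

## Permutation inference

- **p-value convention**: `p = (b+1)/(m+1)`, `b` = permutation statistics
  at least as extreme, `m = 10,000` by default; the floor 1/10001 prints
  as 0.0001. (The natural-language definition of the p-value in the source
  methods is self-contradictory; the add-one convention reproduces the
  reported floor.) Two-sided `perm_p` doubles the smaller tail, capped at
  1. The permutation t-test instead counts `|t_null| ≥ |t_obs|`: its null
  is symmetric, the two conventions agree in distribution, and the |t|
  count is standard.
- **Representation test**: cluster labels shuffled over all fish, group
  membership fixed; per-cell two-sided p by doubled smaller tail (default)
  or by the `|count − expected|` tail (`two_sided="abs"`); BH-FDR across
  all cells. On discrete counts the doubling convention is deliberately
  conservative (measured type-I ≈ 0.025–0.03 at α = 0.05); the `abs`
  convention sits on the nominal level.
- **Overlap score**: all unordered exposure pairs with equal labels. The
  published score ranges (1–10 for five exposures, 2–15 for six, the
  latter a pigeonhole bound with four clusters) force the all-pairs
  reading over a literal "consecutive exposures" one; exhaustive
  enumeration over 4⁵ and 4⁶ sequences confirms the ranges.
- **Overlap and two-day tests**: nulls permute each exposure's labels
  across fish independently, for all exposures except the first; the null
  mean of the two-day percent overlap is reported as the "permutation
  average".
- **ANOVAs**: between-subject two-way F from least-squares model
  comparisons (Type II); main effects tested by unrestricted permutation
  of the response, the interaction by Freedman–Lane permutation of
  main-effects-model residuals. The mixed design (one between, one within
  factor) uses the classical univariate decomposition — between effect
  against subjects-within-groups, within and interaction against the
  subject × level residual; exact for balanced group sizes, the
  unweighted-means approximation otherwise; incomplete within-subject data
  are rejected. Permutation schemes: between — subject labels (equivalently
  subject rows); within — each subject's level order; interaction —
  double-centered residuals permuted across subjects and within rows with
  both main-effect layers re-added. Observed F values are cross-checked
  against statsmodels (`anova_lm`, typ=2) and pingouin (`mixed_anova`) in
  the tests; nulls are batch-vectorized.
- **BH-FDR**: statsmodels step-up implementation behind `fdr_adjust`;
  note BH adjustment is not idempotent (BH([0.25, 1]) = [0.5, 1] but
  BH([0.5, 1]) = [1, 1]), so the tests assert monotonicity and bounds.
- **Spearman CI**: percentile bootstrap over paired resamples (10,000 by
  default); degenerate resamples with constant ranks are dropped from the
  percentile computation.

## Reproducibility

Every stochastic routine takes an explicit seed; the pipeline fans one
root seed out to stages by fixed offsets and records a JSON manifest
(config snapshot, seeds, version, per-stage counts). Model serialization
writes floats as `%.17g` and reads them with round-trip parsing so
save → load → save is byte-identical. Type-I calibration of every
permutation test is verified at 1000 null replicates per effect against
the band [0.03, 0.07] at α = 0.05 (replicate count chosen so Monte-Carlo
error, SE ≈ 0.007, is small against the band half-width; each replicate
draws its permutation seed from the test's root generator, since reusing
one permutation stream couples replicates).

## Limitations

- Video-domain processing (pose estimation, depth-map filtering) is out of
  scope; traces enter as located 3D points.
- The movement model is a minimal correlated random walk; it spans the four
  archetype profiles but is not a biomechanical model of swimming.
- The mixed-ANOVA F is approximate for unbalanced group sizes, and the
  residual-permutation interaction null is itself an approximation (mildly
  conservative in the between-subject design, measured ≈ 0.033–0.043).
- 2-D embeddings, chord diagrams, and alternative community algorithms
  (Leiden, spectral) are deliberately not provided.
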