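# Methods

## Tree model and ingest

A traced villous tree is a rooted chain of 3D center points with local
diameters. Points of degree >= 3 are branching nodes; maximal node-free
chains are branches; a branch either ends at a node or at a free distal tip
(terminal end). The proximal cut end where tracing started is the root and
is never treated as a terminal end. Interchange is SWC
(`id type x y z radius parent`, micrometers); the model stores diameters
(2 x radius) because villous morphology is conventionally reported as
branch diameter. Coordinates are taken as isotropic micrometers; no axis
scaling is applied at read time.

Ingest rules: duplicate ids, missing parents, multiple roots, cycles,
disconnected points and non-positive radii are format errors naming the
offending line. Coincident consecutive points — common in hand tracings —
are merged with a logged warning rather than rejected. Degree-2 points are
interior samples of a branch, never branch boundaries, so the branch
decomposition is invariant under permutation of SWC rows and under
round-tripping through `write_swc` (branch ids are regenerated; all
measurements are preserved).

## Terminal distance ordering

`order(b) = 0` if b ends at a terminal end, else
`1 + min over child branches of their order`. This is the
distance-in-nodes from the branch's distal end to the nearest terminal end
of the subtree. It is computed from topology alone and is checked in the
tests against an exhaustive enumeration of all downstream paths.

## Branch geometry

- Length: polyline length of the centerline.
- Direction: the chord from proximal to distal endpoint. The planar
  branching angle between branch and parent is the angle the two chords
  span, `arccos` of the normalized inner product, in [0, 180] degrees; 0
  means continuation without change of direction. The chord convention is
  the default because a branch's direction is defined by its endpoints; a
  local-tangent variant (`angle_convention: tangent`, using the two
  segments meeting at the shared node) is provided for sensitivity
  analysis since tracing software may use either.
- Tortuosity: length / straight endpoint distance, >= 1 and exactly 1 iff
  the samples are collinear. Coincident endpoints make the ratio undefined
  and raise a degenerate-geometry error.
- Surface and volume: each inter-point segment is a conical frustum with
  end radii r1, r2 and height h; lateral surface pi (r1+r2) sqrt(h^2 +
  (r1-r2)^2) and volume pi h/3 (r1^2 + r1 r2 + r2^2). End caps are
  excluded: they are internal cross-sections of a continuous villus, and
  excluding them makes both measures exactly invariant under subdividing a
  straight, linearly tapering branch (asserted to 1e-9 relative error).
  Whether published villous surface/volume figures included caps is not
  generally verifiable; excluded here by design.
- Mean diameter: length-weighted mean of segment mean diameters (also
  subdivision-invariant).

All measures are invariant under rigid motions (asserted under random
rotations + translations).

## Aggregation

Per specimen and order k in {0, 1, 2}, each metric is the unweighted
arithmetic mean over all branches of that order across the specimen's
trees (several trees per specimen are pooled before averaging). Absent
values are skipped: the root branch contributes no angle; a mean is absent
altogether when no branch of that order exists — small trees frequently
lack bT2 branches. Orders >= 3 are measured and present in the per-branch
table but excluded from the group statistics, which use bT0-bT2 only.
Aggregated means are unweighted (not length-weighted) because the
per-placenta summary is defined as the individual mean over branches.

## Statistics

- Kruskal-Wallis: tie-corrected H on midranks,
  `H = [12/(N(N+1)) sum R_j^2/n_j - 3(N+1)] / [1 - sum(t^3-t)/(N^3-N)]`,
  p from the chi-square approximation with (groups - 1) df. All
  observations identical gives H = 0, p = 1.
- Dunn's post-hoc: for each pair,
  `z = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - sum(t^3-t)/(12(N-1))] (1/n_i + 1/n_j))`
  on the joint ranks, two-sided normal p, then a multiplicity adjustment
  over all pairs — Bonferroni by default (the most common convention after
  Kruskal-Wallis), `none` and `holm` configurable. Reports carry both raw
  and adjusted p-values, and stars (*/**/***) are rendered from the
  adjusted ones at 0.05 / 0.01 / 0.001.
- Student's t (pooled variance, default) and Welch's t for two-sample
  comparisons of approximately normal quantities (e.g. macroscopic
  validation variables). Zero variance in both samples: p = 1 for equal
  means, p = 0 (flagged) otherwise. All tests are two-sided.
- HT/LT split: clinically normal specimens with mean bT1 tortuosity
  strictly above the threshold (default 1.2) are HT-normal, below it
  LT-normal; a value exactly at the threshold is labeled LT-normal with a
  warning, because the subgroup is defined by "more than" the cutoff.
  Specimens without bT1 branches are excluded from the split and logged.
  IUGR specimens are never relabeled.
- Angular summaries: rose histogram over 360 degrees (default 10-degree
  sectors); mode detection on a Gaussian kernel density wrapped on the
  circle, evaluated on a 1-degree grid (binning alone cannot localize
  1-degree maxima), default bandwidth 4 degrees, local maxima closer than
  the bandwidth merged into the higher one; Hartigan's dip statistic with
  a Monte-Carlo p-value. Angular analyses run on per-placenta mean bT0
  angles (one value per placenta), matching how the group summaries are
  defined, not on pooled branch angles.

### Hartigan's dip

The dip is the minimum over unimodal distribution functions of the maximum
absolute distance to the empirical CDF. It is computed by the
greatest-convex-minorant / least-concave-majorant iteration on the sorted
sample: on the current candidate modal interval, the lower convex hull of
the left-limit ECDF points and the upper concave hull of the right-limit
points are formed; the interval shrinks to the hull touchpoints bracketing
their largest mutual gap, while the convex and concave flanks contribute
their maximal deviation from the ECDF (the new modal endpoint's own jump is
excluded, since a unimodal law may carry an atom at its mode); the dip is
half the largest deviation encountered. Identical samples give 0; two equal
spikes give the maximal value 0.25. The implementation is validated
exhaustively against an independent linear-programming oracle that
minimizes the sup-distance over piecewise-linear unimodal CDFs with a
grid-searched mode, and against closed-form values (equally spaced samples
give 1/(2n)).

p-values come from a seeded Monte-Carlo null — the fraction of `n_boot`
(default 10,000, minimum 1,000) uniform(0,1) samples of equal size with dip
at least the observed one — rather than from interpolation tables; the dip
is scale-free, so the uniform null serves any sample. Nulls are cached per
(n, n_boot, seed) within a process.

### Small-sample accuracy

The chi-square (KW) and normal (Dunn) p-value approximations carry
appreciable small-sample error: at 4 observations per group they deviate
from the exact permutation null by up to ~0.05 in the mid-p range, shrinking
to ~0.005-0.015 at 15 per group. The test suite therefore compares p-values
against seeded permutation oracles at 15 per group, where Monte-Carlo error
(2,000 resamples) dominates the residual approximation error, and separately
asserts exact equality of the H and z statistics against independently coded
oracles on random small samples. With cohorts of 14-40 specimens per group,
as here, the approximation is adequate; for much smaller groups the
permutation p-value should be preferred.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline is designed
to detect, with ground truth recorded before geometric realization.

- Cohort: 40 IUGR + 50 clinically normal specimens, the normals split
  14 HT / 36 LT (28% HT). The manifest labels HT/LT specimens plainly as
  "normal"; the pipeline must rediscover the split.
- Terminal angles: per group a mixture of normal components on degrees —
  IUGR 58/76, LT-normal 52/64 (equal weights), HT-normal single 67. The
  mixture acts hierarchically: each specimen is assigned a component
  (largest-remainder stratification, so realized counts match the weights
  exactly), draws its own center with between-placenta sd 2 degrees, and
  each branch draws N(center, 6 degrees) truncated to (0, 180). The
  hierarchy matters: the rose diagrams summarize per-placenta means, so
  bimodality must exist across specimens, not merely across branches; the
  2-degree between-placenta spread keeps 12-degree-separated components
  resolvable by a 4-degree-bandwidth kernel at cohort size.
- Tortuosity at bT1: IUGR and LT-normal targets from N(1.08, 0.04)
  truncated to [1.0, 1.2]; HT-normal from N(1.28, 0.05) truncated to
  [1.2, 1.6]; other orders N(1.05, 0.03) capped below 1.2. Because every
  HT draw exceeds 1.2 and every LT/IUGR draw stays below it, the specimen
  means separate deterministically at the cutoff.
- Geometry: a branch is realized as a polyline whose chord lies exactly
  along the drawn direction (child chords are placed at exactly the drawn
  branching angle, uniform azimuth), with a sinusoidal out-of-chord
  perturbation whose amplitude is solved by bisection until the polyline's
  own measured tortuosity equals the target (~1e-9); measured angles and
  tortuosities therefore round-trip through the measurement operations
  essentially exactly.
- Sizes: terminal-end count 1 + Poisson(11) per tree (mean 12, comparable
  to a traced peripheral bush); branch lengths per order with means
  80/100/120/140 um (sd 25%) for bT0..bT3+; HT-normal bT1 lengths +40% and
  diameters +10% relative to LT-normal, which propagates into higher
  surface and volume means — mirroring the direction of the published
  group differences without claiming unpublished magnitudes. Base distal
  diameter N(60, 8) um, widening 15% per order proximally. These scales
  are realistic for peripheral villi (terminal villous diameters of tens
  of micrometers); no published distributional parameters exist for them,
  so they are conventions, editable per profile.
- Topology: strictly binary nodes by default (a trifurcation probability
  field is reserved). With group-specific probability `prob_no_bt2` (0.45
  IUGR, 0.22 normal — the published fractions of trees lacking bT2) a tree
  is grown as a caterpillar, in which every internal branch is directly
  preterminal and no bT2 branch exists; otherwise the root split leaves at
  least two terminals on both sides, guaranteeing a bT2 branch. The
  realized no-bT2 fraction is thus Binomial(prob) exactly.
- Determinism: each specimen derives its substream from (seed, running
  specimen counter), so identical seeds give byte-identical cohorts and
  cohorts are extensible without reshuffling earlier specimens.

What the generator does *not* emulate: tracing noise (z-shrinkage,
refraction, operator variability), anatomically realistic spatial packing
(generated branches may intersect in space), angiogenesis dynamics, and
any coupling between angle and tortuosity regimes beyond group membership.
Passing recovery tests therefore demonstrates that the measurement and
statistics machinery is correct and powered at realistic cohort sizes —
not that real placentas satisfy the generator's distributional assumptions.
Terminal-distance order is also not monotone along root-to-tip paths, so
the per-order diameter widening occasionally produces a distally widening
branch; this does not affect any tested quantity.

## Pipeline

`run_study` is a pure function of (manifest contents, SWC bytes, config):
reports carry no timestamps, JSON keys are sorted, and input/table SHA-256
digests are recorded in the provenance block, so identical runs are
byte-identical. Invalid trees exclude their specimen with a logged reason
(itemized in the report); a run aborts only if no specimen survives.
Specimens lacking a metric at some order are dropped per test (pairwise
deletion), never imputed. The two-group (IUGR vs normal) and three-group
(IUGR / HT-normal / LT-normal) batteries read from the same written
aggregate table, and the two-group comparison reports both Student's t and
the rank-based test, since either may be the convention of interest.

Default problem sizes in the test suite: the full 90-specimen default
cohort for recovery and determinism checks; 200 trees per profile for
mixture-mean recovery, at which the Monte-Carlo standard error of a
component mean (~0.26 degrees) sits well inside the 1-degree recovery
band — at 14-40 specimens per group the per-component SE is 0.5-0.7
degrees, so cohort-sized recovery to 1 degree would not be a powered test
of correctness.

## Known limitations

- The chi-square/normal p-value approximations are the reported ones even
  at small n (see above); permutation alternatives exist only as test
  oracles.
- The dip test's Monte-Carlo p-value has resolution 1/n_boot.
- Angle conventions of specific tracing software may differ from both the
  chord and tangent variants offered.
- SWC files with a branching root point are rejected rather than repaired:
  the proximal cut end must begin a single branch.
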