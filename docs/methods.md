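# Methods

## The tissue model

A tissue is represented as a labeled planar graph. The geometric substrate
(the *tissue scaffold*) is produced by random circle packing: circles with
radius drawn uniformly from `[r_min, r_max]` are placed at uniform random
positions inside a rectangle, rejected if they overlap any placed circle
(strict overlap; tangency is allowed), and placement stops after 500
consecutive rejections, leaving a near-saturated packing. Circles are cells.
Two cells are adjacent when their circles come within `r_min` of touching,

    d(u, v) < r_u + r_v + r_min ,

a criterion symmetric in the two circles. Nodes sit at circle centers; edges
connect adjacent cells.

Cell-type information lives on the nodes and is parameterized by a
proportion vector `p` (length K, sums to 1) and a row-stochastic
neighborhood matrix `H` whose entry `(i, j)` is the probability that a
neighbor of a type-`i` cell is of type `j`. For a labeling encoded as a
one-hot assignment matrix `B` (n x K), the observed neighborhood matrix is

    H(B) = diag(B^T B)^-1  B^T  diag(A A^T)^-1  A B ,

i.e. each node's neighbor-type fractions averaged within type. Rows of
`H(B)` sum to one on graphs without isolated nodes; isolated nodes
contribute a zero row and a type with no cells leaves its row undefined
(an error in the public evaluation).

### Scaffold defaults

The paper-scale tissue is a 500 x 500 px region holding roughly 2,200 cells
(the cell count of a typical 500 x 500 um tissue-microarray core). The
default radius bounds `r_min = 2.9`, `r_max = 6.0` px were calibrated to
produce that density; the realized packing fraction at the default stopping
rule is about 0.47 for this radius mix. `scaffold_for_count` inverts the
empirical yield `n ~ 0.0733 * area / r_min^2` (measured at the default
radius ratio) to pre-size a scaffold for a target cell count; acceptance
favors small circles, so this measured yield — not the uniform candidate
radius distribution — is the right calibration. Coordinates are continuous,
origin at the lower-left corner, and carry no unit conversion (px-to-um
mapping is user metadata).

## Labeling engines

**Heuristic.** The region is partitioned into a 50 x 50 px grid. In each
partition a random start node takes a type drawn from `p`, and its
neighbors within geodesic distance `epsilon = 1` take types drawn from the
corresponding row of `H`. The grid is shifted by 25 px and the pass
repeated; remaining unlabeled nodes are labeled by the same
start-and-spread process. Nodes labeled earlier are never relabeled, which
prevents oscillation. A correction pass then proposes random pairwise label
exchanges and accepts a swap only if it strictly decreases the L1 deviation
`||H_obs - H||_1`, so the deviation is non-increasing; swaps preserve the
graph and the label multiset exactly. The loop stops when every entry of
the deviation is within `tol = 0.02` or after `max_iters` (default 500;
a few thousand iterations visibly help strongly structured targets).
Extreme targets (e.g. diagonal 0.9) are near the graph-coloring regime and
are approached but not met exactly; moderately structured targets
(diagonal around 0.6) are recovered to a mean absolute entry error well
below 0.05 at ~2,000 cells.

**Optimization.** A continuous assignment matrix is fitted by minimizing

    -Trace(H(B)^T H*) + l1 ||B 1_K - 1_n||_2 + l2 ||colsum(B)/n - p||_2

with plain gradient descent (analytic gradient, verified against finite
differences in the test suite), starting from a row-softmax of i.i.d.
Gaussian noise and projecting entries onto [0, 1] after each step. The
proportion residual is expressed on the proportion scale
(`colsum(B)/n - p`), which differs from a raw column-sum residual only by a
rescaling of `l2`. When per-type weights `w_k` are supplied the proportion
term becomes `l2 * sum_k w_k (colsum_k/n - p_k)^2`, letting rare types be
held to their target proportion; the `extreme_values_only` flag restricts
the proportion constraint to entries of `p` more than one sample standard
deviation from the mean of `p`. Defaults: `l1 = l2 = 1`, learning rate
0.01, 2,000 iterations; the best iterate by recorded loss is returned.

Two numerical choices matter. First, the per-type mass `diag(B^T B)` is
floored at one cell inside the optimizer's objective: without the floor the
trace term is unbounded below (a vanishing column makes `H(B)` blow up) and
gradient descent chases that degenerate direction instead of a labeling.
The public `neighborhood_matrix` is unchanged and raises on degenerate
types. Second, discretization rounds each row by argmax with ties broken
toward the lowest type index (or samples each row, seeded).

The relaxed problem is closely related to k-graph-coloring and need not
reach arbitrary `(p, H)` targets; on small instances (e.g. a 4-cycle with a
perfectly anti-assortative target) the optimizer recovers the exact
optimum, confirmed by exhaustive enumeration in the tests. The heuristic
engine is the practical default for large tissues.

## Detection models

Three sampling strategies map to three models; all return the probability
of observing at least `n_min` cells (default 1) of a target type.

* **Single-cell sampling** (dissociated profiling): Binomial(n, p). The
  minimum cell count for a target probability has the closed form
  `ceil(log(1 - target) / log(1 - p))` at `n_min = 1`. An optional
  false-discovery-rate parameter multiplies the abundance by `(1 - FDR)` to
  model cell-type miscalling.
* **Spatial (FOV) sampling**: per-FOV counts of the type are overdispersed
  by tissue structure and modeled as gamma-Poisson (negative binomial) with
  mean `m` and shape `k`. The mean is the sample mean; the shape is fitted
  by the zero term method (ZTM), solving `n0/N = (m/k + 1)^-k` for `k` by
  bracketed root finding on `[1e-3, 1e6]`. When the observed zero fraction
  is at or below the Poisson floor `exp(-m)` — including samples with no
  zeros — the equation has no root and the moments estimator
  `k = m^2 / (s^2 - m)` is used, with the shape capped at `1e6` (the
  Poisson limit) for under-dispersed samples. Detection over `n_FOV`
  independent FOVs is `1 - P(X = 0)^n_FOV`, and the FOV requirement is the
  smallest count reaching the target.
* **Regional sampling** (FOVs drawn, dissociated, cells profiled):
  beta-binomial with `alpha = mu (mu(1 - mu)/sigma - 1)` and
  `beta = (1 - mu)(mu(1 - mu)/sigma - 1)`, where `mu` and `sigma` are the
  sample mean and variance of per-FOV *proportions* of the type (counts
  normalized by FOV totals — the only reading under which `alpha, beta > 0`
  is dimensionally coherent). Fitting draws 50 FOVs of 5% tissue area by
  default; under-dispersed samples (`sigma >= mu(1 - mu)`) are rejected
  with a pointer to the binomial model. Detection uses the beta-binomial
  survival function at `n_min - 1`.

FOVs are square, fully contained in the tissue bounds, and drawn
independently (overlap permitted) — consistent with raising the per-FOV
zero probability to the `n_FOV` power. The cohort-size calculator inverts
`1 - (1 - q)^n >= target` for the number of tissue samples needed to
observe a feature whose per-tissue detection probability is `q` (e.g. the
fraction of replicate ISTs in which an adjacency was significant).

## Adjacency statistics

**Permutation test.** Labels are shuffled on the fixed graph (preserving
the multiset and the degree sequence); `H(B)` is recomputed per shuffle and
each entry scored one-sidedly as

    P = (n_trials - #{strictly more extreme shuffles} + 1) / (n_trials + 1) ,

so ties favor the null and the smallest attainable p-value is
`1/(n_trials + 1)`. Raw p-values are reported (the framework's worked
analyses use P < 0.01); a Benjamini-Hochberg column is available but never
substituted silently. Default 1,000 shuffles, seeded.

**AES.** For types A and B the adjacency enrichment statistic compares the
observed A-B edge count with the proportion-based expectation:

    Sigma = 2 f_A f_B |E| ,    AES = N_AB / Sigma - 1 ,

computed for all pairs at once via `C = B^T A B` (off-diagonal entries are
cross-type edge counts; the diagonal is halved). The formula is applied
verbatim for A = B, where `Sigma = 2 f_A^2 |E|` is twice the natural
same-type expectation — a documented property of the printed statistic, not
corrected here. Pairs with `f_A f_B = 0` are marked undefined (NaN), not an
error. The exact permutation mean of the AES is `+1/(n - 1)` rather than
zero (the expectation uses unordered pair counts), which is negligible at
the ~2,000-cell scale the tests use.

Per-FOV AES distributions are computed on FOV-induced subgraphs (both
endpoints inside the FOV; nothing outside a FOV is observable). FOVs
missing either type of the pair, or containing no edges, leave the
statistic undefined and are excluded, with the exclusion count reported.
The Gaussian fit is maximum likelihood: sample mean and 1/n variance. Two
distributions are compared with

    z = (mean1 - mean2) / sqrt( sd1/sqrt(n1) + sd2/sqrt(n2) ) ,

exactly as printed (standard deviations over root-n summed under one
root), with a one-sided Gaussian p-value; the conventional two-sample
statistic is available separately as `welch_z_test` and never silently
substituted.

**Clustering.** Per-tissue significance profiles (flattened p-value
vectors) are clustered by UPGMA (average linkage, Euclidean distance) via
scipy; deterministic.

**Adjacency reduction.** To build a tissue differing only in one pair's
adjacency frequency, labels are exchanged between an endpoint of an A-B
edge and another node of a different type: the graph and the type
histogram are untouched while the A-B edge count moves. Swaps are accepted
greedily while they bring the count closer to `(1 - reduction)` of the
original; the edit stops within half an edge of the target when possible
and errors (reporting the best reduction achieved) if it cannot get within
2% of the original count.

## Mosaics and spatial resolution

Whole-slide tissues with annotated gross morphology are emulated by a tile
map: the tissue is gridded, each tile takes the modal region label of its
cells (empty tiles inherit the nearest non-empty tile's zone by Chebyshev
distance, ties toward the lowest label), and `(p, H)` are estimated per
region from the region-induced subgraph. One blank scaffold sized to the
mean cells per tile is generated once and relabeled independently per tile
with its region's parameters, then translated into the composite frame.
Tiles are graph-disjoint: cross-tile adjacency is never defined, which is a
documented limitation for whole-mosaic adjacency testing (per-tile and
per-region statistics are unaffected). Tile shuffling permutes tile
positions uniformly while preserving per-zone tile counts, randomizing
macrostructure.

Resolution degradation bins cells onto a triangular lattice of spots
(rows along x, odd rows offset by half the pitch, row pitch
`spacing * sqrt(3)/2`, origin at the bounding-box corner, one extra
row/column beyond each edge so boundary cells can be captured). Defaults
follow the Visium-like geometry: 100 um pitch, 27.5 um capture radius; the
radius must stay below half the pitch so assignment is unambiguous. Cells
outside every capture radius are discarded; assigned plus discarded equals
the total. On spatially uniform tissue the retained fraction approaches
the lattice coverage `pi r^2 / (s^2 sqrt(3)/2) ~ 0.274`, slightly reduced
by boundary exclusion. A spot is a *spot of interest* for a type when
strictly more than 10% of its member cells are of that type — a threshold
standing in for realistic cell-type deconvolution error; the FOV power
pipeline then runs on qualifying spot centers instead of cells. When no
sampled FOV is empty of qualifying spots the zero-anchored estimate of a
blank FOV is zero and a single FOV suffices.

## What the synthetic generator does and does not emulate

The generator reproduces cell-type composition, pairwise adjacency
preference, regional mosaic structure, and realistic cell counts per area.
It does not model variable cell density (density is set by the packing and
is spatially homogeneous), cross-tile adjacency, 3-D structure,
non-rectangular domains, marker-level noise, or segmentation error. Tests
passing on these tissues therefore demonstrate correctness of the
statistical machinery and calibration under the stated model, not
robustness to density gradients or segmentation artifacts in real data.
Real cell tables enter through the reader plus a pluggable graph builder
(Delaunay with a length cutoff, or a fixed-radius rule); how adjacency was
defined in any particular published dataset is the user's modeling choice.

## Reproducibility and problem sizes

Every stochastic routine takes a seed; a run configuration expands one
global seed into per-stage child seeds through named `SeedSequence`
spawns. The bundled analyses use a 500 x 500 px scaffold (~2,200 cells),
100 FOVs per fit, 50 replicate labelings for the rare-cell FOV
requirement, and 199-1,000 permutation trials depending on the analysis —
sizes chosen so each statistical check has comfortable resolving power at
its tolerance. Rendering uses Voronoi tessellation up to 20,000 cells and
falls back to a scatter plot above that, where the tessellation becomes
slow.
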