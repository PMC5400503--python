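# Methods

This note documents the models, conventions and design choices behind
the package, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and unit conventions

All internal coordinates are micrometres in continuous physical space.
Voxel→µm conversion happens only at ingest (NML files carry a per-file
nm-scale element; the conventional EM voxel is 11 × 11 × 29 nm).
Branch-node and axonal synapse densities are reported per mm; dendritic
spine and synapse densities per µm; whole-nucleus constants use m (axon
path) and mm³ (volume). Fragment lengths *l* are mm, soma distances *r*
and the length constant λ are µm — the combination Db(r)·l is then a
dimensionless Poisson mean.

## Skeleton morphometry

A skeleton is an undirected forest with per-node positions, radii and
compartment tags. Path length sums Euclidean edge lengths over edges
whose **both** endpoints pass the compartment filter.

Radial ("spherical Sholl") profiles use Euclidean distance from the soma
centroid; geodesic distance is available but not the default — the
radial profiles that feed the density model are spherical by
construction. Each edge's length is apportioned across distance bins by
linear interpolation of the radius along the edge, so a profile sums to
the filtered path length exactly (conservation is a test invariant).
This removes the bin-assignment bias of midpoint binning for long edges;
the linear-radius approximation along an edge is exact for radial edges
and second-order accurate otherwise, negligible at ~1–2 µm edge lengths.

Branch nodes are degree-≥3 nodes, excluding nodes where any daughter
subtree extends less than 15 µm beyond the node (maximum *path*
extension, not straight-line distance — consistent with path-length
reporting). Daughters are defined relative to the tree rooted at the
soma node, or at each component's minimum node id when no soma exists.

LM post-processing replaces each interior node's z-coordinate by the
mean over itself and up to four neighbors each way along its unbranched
run (windows shrink near branch points and tips), then resamples each
run to ~1 µm spacing. Branch points and tips keep their coordinates, so
topology is preserved exactly; resampling may shorten wiggly paths by a
few percent, which is the intended noise suppression.

## Soma-distance inference

**Density model.** Db(r) = A·exp(−r/λ) + c with A, c ≥ 0, λ > 0.
Fitting is weighted nonlinear least squares (scipy `curve_fit`,
weights = per-bin path length, i.e. sigma ∝ 1/√path) with a multi-start
over λ ∈ {10, 50, 200} µm keeping the best SSE. For constant data the
amplitude collapses to ~0 and λ is flagged unidentifiable
(`lambda_identifiable=False`) rather than reported as meaningful.

**Likelihood.** Poisson log-pmf computed via log-gamma, stable for N up
to at least 10⁴. A fragment is treated as sitting at a single r; no
integration over intra-fragment r variation (fragments are short
relative to λ at the distances of interest).

**Prior.** Axon path is sampled at ~1 µm spacing (each edge contributes
ceil(len/spacing) points, so weight is proportional to local path), the
soma distances are smoothed with `scipy.stats.gaussian_kde` (Scott
bandwidth), and the density is evaluated on the grid with reflection at
r = 0 — mass that would leak to negative distances is folded back, which
preserves total mass and avoids boundary bias. The grid is 0–700 µm in
1 µm steps: it covers the long axis of the nucleus at negligible cost,
and the 1 µm step is far below every posterior width we observe.

**Posterior.** Pointwise product of the likelihood (max-subtracted in
log space) and the prior mass, renormalized; mean/median/variance and
quantiles by linear interpolation of the discrete CDF. Calibration is
checked generatively: fragments drawn from the prior with Poisson counts
from the model must be covered by the central 68% interval at 68 ± 10%
(the observed slight over-coverage is the usual discreteness effect of
integer counts).

**Nearest-neighbor sampler.** Reference arbors are chopped by a grid of
EM-shaped cells (default 166 × 166 × 77 µm³) whose origin is shifted in
10 µm increments along all three axes (ceil(box/shift) placements per
axis — 17 × 17 × 8 for the default box). Every maximal axon piece
within a cell is recorded as (N, l, r) where r is the path-length-
weighted mean Euclidean soma distance of the piece (stabler than the
midpoint for long pieces; midpoint distance differs by < the piece's
radial spread). Only pieces that both enter and leave their cell (≥ 2
boundary cut points) are kept, matching how orphaned fragments present
in a real EM volume. Matching is exact in N and ±10% in length, with no
silent widening: an empty match set is returned explicitly. Tie-break:
a grid plane passing exactly through a skeleton node separates pieces
without recording a cut point; this is measure-zero for real-valued
coordinates and only matters for artificially integer-aligned data.

## Cell typing

Spines are side branches off the dendritic shaft longer than 1 µm
carrying at most one synapse (multi-synapse protrusions are interneuron
features, not spines). The shaft is taken as the longest path through
each component, and the spine-density denominator is shaft length —
protrusion path is excluded so geometric spines do not dilute their own
density. Threshold classification uses 0.11 and 0.46 µm⁻¹ with the
boundary convention that an exact threshold value goes to the
higher-density class (measured densities are continuous, so the
convention is inconsequential but fixed for testability); stretches
shorter than 10 µm return "unknown".

Same-cell merging computes, for each ordered pair, the share of one
skeleton's nodes within 400 nm of any edge of the other (exact
point-to-segment geometry), links the pair when either direction reaches
25%, and takes connected components — transitive and
permutation-invariant by construction. Per-group spine density is the
unweighted mean of member densities, averaged before classification
(the length-weighting of that average is not specified by the source
analysis; equal weighting is the simplest defensible choice).

## Census estimators

Cube sampling places n cubes uniformly with the cube fully inside the
volume (sampling with replacement, seeded) and measures labeled axonal
path by exact segment–box (slab) clipping. Labeling efficiency is
observed density / (total path / reference volume); the density deficit
ratio is its reciprocal. First-order error propagation assumes
independent inputs: relative variances add for products and ratios,
absolute variances with squared coefficients for linear combinations.
Poisson counts use √k SEM with an upper bound of 1.84 for k = 0 (a
simple Feldman–Cousins-style choice; the k = 0 handling only affects
degenerate tallies). Binomial proportions use √(p(1−p)/n). Every
`CensusResult` records its inputs (value, error, and whether the error
was an SD or SEM), making each estimate a pure, replayable function of
its audit record.

The two homotypic-fraction perspectives are reported without
reconciliation: the dendritic estimate (double-labeled count / total
excitatory / efficiency) and the axonal estimate (outgoing per cell ×
RA target share / incoming excitatory per cell) answer the same
question through different measurements, and their agreement is itself
a consistency check exercised on synthetic circuits.

## Synthetic circuit generator

The generator reproduces the *summary statistics* the analysis consumes,
not arbor biophysics:

- **Axons** grow as persistent random walks (2 µm steps, Gaussian
  direction perturbation σ = 0.25, reflecting walls) that bifurcate with
  probability Db(r)·Δs per step — an inhomogeneous Poisson branch-node
  process with exactly the configured intensity. Reflection keeps the
  stationary path density approximately uniform over the volume, which
  the stereology tests rely on.
- **Dendrites** are radial shoots from the soma with exponentially
  distributed lengths (scale 30 µm), tuned so ~95–96% of dendritic path
  lies within 100 µm of the soma. They are star-shaped, not branched:
  sufficient for radial profiles, spine densities and path totals, and
  deliberately not a model of dendritic topology.
- **Synapses** are a homogeneous Poisson process along the axon
  (default 75.4 mm⁻¹); each synapse's target class is drawn from a
  logistic-in-r mixture normalized so the interneuron share is exactly
  0.95 at r = 0 and 0.354 far away, with the RA share rising from 0.033
  to 0.369 (endpoints pinned to the observed proximal and distal target
  tallies; the logistic shape between them is a stand-in). Active-zone
  areas are lognormal around a 0.17 µm² median.
- **Labeling** is Bernoulli per cell (default 1/7 of somata) followed by
  per-branch dropout calibrated so the overall axon-labeling probability
  hits a configured value (default 0.076). Incoming-synapse bookkeeping
  (homotypic inputs from the generated synapse table plus Poisson
  external excitatory counts, default 595 per cell = incoming excitatory
  786 minus the homotypic expectation) gives a known true homotypic
  share for recovery tests.

What passing tests on this generator show: the estimators are unbiased
and their error models calibrated *under the stated assumptions*
(independent Poisson placement, distance-stationary mixtures, spatially
near-uniform arbors). What they cannot show: robustness to real-arbor
features the generator lacks — fasciculation, boundary-avoiding
trajectories, correlated branching, non-circular active zones.

## Problem sizes and numerical choices

Test circuits use volumes of 80–600 µm per side, 1–160 cells and
0.3–8 mm of axon per cell; the stereology recovery uses 300 cubes × 20
replicate circuits (160 cells each, so per-cell Bernoulli labeling
variance stays small relative to cube noise), and posterior calibration
uses 500 fragments. These sizes keep the full suite near two minutes on
one CPU while leaving every statistical tolerance comfortably wider than
the corresponding Monte-Carlo error. Posterior computations subtract the
log-likelihood maximum before exponentiating; a zero-mass posterior
raises rather than returning NaNs. Resampling of a polyline uses
round(total/spacing) intervals so realized spacing brackets the request.

## Known limitations

- The fragment likelihood conditions on a single r; fragments spanning a
  large radial range are summarized by their path-weighted mean.
- The branch library records pieces per grid cell independently across
  placements, so the library oversamples long pieces ~box/shift times;
  this mirrors the shifted-division design rather than correcting it.
- `merge_same_cell` is O(n² · nodes × edges); adequate for tens of
  reconstructions, not thousands.
- The generator's dendrites carry no synapse geometry; incoming-synapse
  statistics are count-level, which is all the census consumes.
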