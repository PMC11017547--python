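# Methods

## The access metric

The unit of analysis is the census tract; the unit of measurement is the
census block.  Every block centroid and every pharmacy is snapped onto the
road network by perpendicular projection to the nearest edge (falling back
to the nearest endpoint when the projection leaves the segment; exact ties
resolve to the lexicographically smallest edge key).  A snapped point splits
its host edge into two traversable half-edges, so distances are measured
from mid-edge positions, not from the nearest junction — on coarse networks
this matches how GIS network analysts compute facility distances much more
closely than node snapping does.

The block distance `d_b` is the shortest path length along the network from
the block's snap location to the nearest in-scope pharmacy's snap location.
It is computed with one multi-source Dijkstra sweep over a copy of the graph
in which every in-scope pharmacy is inserted as a real node (pharmacies
sharing an edge form a chain); a query point's distance is then the minimum
of (distance to either host-edge endpoint plus the along-edge offset) and
any direct along-edge gap to a pharmacy on the same edge.  This is
contractually identical to the minimum over per-pharmacy single-source
searches, and the test suite checks that equality against an independent
brute-force oracle on random graphs.

Two deliberate choices, both kept visible in the outputs:

* **Snap displacement is not added to the distance.**  The straight-line gap
  between a centroid and the road is reported per block
  (`snap_displacement_km`) for QC, but the access metric is pure network
  length.  Whether a GIS tool adds that gap is tool-specific; excluding it
  keeps the metric well-defined and the choice auditable.
* **Unreachable blocks are flagged, never averaged.**  A populated block on
  a network component with no in-scope pharmacy gets an infinite distance;
  any tract containing one is excluded with reason `unreachable` and a
  warning, rather than silently contaminating a weighted mean.

The tract statistic is `PWMSD_t = Σ pop_b·d_b / Σ pop_b`.  Zero-population
blocks carry no weight.  A PWMSD of exactly zero (a pharmacy at a populated
centroid's snap location) is floored to 0.001 km before the log transform,
with a warning — ln(0) is undefined and 1 m is far below any meaningful
access difference.

## Exclusions and descriptives

Tracts are excluded in a fixed order: water-only (no land area) first, then
total population < 10, then unreachable; tracts present in the covariate
table but absent from the block table are logged as unmatched and excluded.
The cascade is idempotent and its log records counts at every step.

Descriptive statistics use the sample SD (n−1); "within 1 km" is a strict
inequality; the top/bottom population deciles take floor(n/10) tracts from
each end of the population ranking with ties broken by tract id.  These
conventions are pinned because the quantities are reported to one decimal
and denominator/boundary choices can move that digit.

## The disparity model

Quartiles are rank-based: tracts sorted by (covariate value, tract id) are
partitioned into four contiguous groups as equal in size as possible (any
remainder goes to the lowest quartiles), making the split deterministic
under input permutation and under ties.  Q1 always holds the lowest values
and is always the referent.

The Gaussian-identity GLM coincides with OLS, so the fit is OLS of
ln(PWMSD) on Q2–Q4 indicators — a saturated dummy design whose coefficients
are exactly the quartile means of ln(PWMSD) minus the Q1 mean; the test
suite asserts that identity to 1e−10.  The coefficient covariance is the
heteroskedasticity-consistent sandwich `(X'X)⁻¹X'diag(w_i e_i²)X(X'X)⁻¹`.
HC3 (`w_i = 1/(1−h_ii)²`) is the default because it is the standard
conservative choice of the R sandwich/lmtest ecosystem; HC0 and HC1 are
available for sensitivity and the point estimates are provably identical
across HC types.  Note HC3 is undefined when a design cell contains a
single observation (leverage 1); with n ≥ 8 and near-equal quartiles this
cannot occur.  p-values and CIs use the normal reference (z = 1.96), the
usual convention with sandwich SEs at thousands of observations; at small n
the intervals are mildly anticonservative.

Percent differences are `(e^β − 1)·100`, with CI endpoints transformed from
`β ± 1.96·SE`.  The transform is exact and monotone, so sign and ordering
statements carry over from the ln scale unchanged.  Reported tables print
one decimal; full precision is kept internally.

Binned trend summaries (for income and educational attainment) use
left-closed right-open bins anchored at zero, report per-bin tract counts,
mean PWMSD and mean % white, and split urban/rural at the 75th percentile of
tract population density.  Curve smoothing is presentation and is left to
the caller.

## The synthetic region

The generator emulates the structure that makes the real analysis
interesting: a single urban core.  A square lattice road network (1 km
spacing, ±10% length jitter, 10% random edge dropout constrained to keep
≥95% of nodes in the largest component) covers a 10×10 grid of 2 km square
tracts, each holding 4–8 blocks with log-normal populations whose location
parameter rises with an exponential-decay urban score, so density falls
with distance from the centre.  Tract covariates are linear in the urban
score with Gaussian noise, clipped to valid ranges (% poverty, % Black/AA,
% Hispanic rising toward the core; median income and % white falling);
% higher education is U-shaped in urbanicity.  Default slopes keep
clipping below ~1% of tracts; a warning fires if a configuration clips more
than half.  Pharmacies (80 by default, about one per 1.25 tracts) are sited
proportionally to block population (alternatives: uniform, urban-core), plus
an in-scope band beyond the east edge (neighbouring-state pharmacies) and an
out-of-scope band beyond the north edge (international pharmacies) that must
never affect any distance.  One tract is water-only and two are forced under
10 residents so the exclusion cascade is always exercised.

Each component (network, populations, covariates, facilities) draws from its
own RNG stream spawned from the master seed, so changing one knob never
perturbs the other components; outputs are byte-identical under a fixed
seed, and ground truth (siting rule, slopes, any direct-effect betas) is
written to `manifest.json` alongside the data.

What the generator does *not* emulate: real street topology, multiple urban
centres, spatially autocorrelated covariate noise, ACS sampling error, or
realistic marginal distributions.  Passing tests therefore demonstrate that
the pipeline's arithmetic, exclusion logic and inference machinery are
correct and that the qualitative core-access mechanism is recovered — not
that real-data effect sizes would match.

A separate direct-effect generator bypasses geometry: it assigns quartile
labels evenly, draws `ln(PWMSD) = β0 + Σ βk·I(Qk) + N(0, σ)`, and emits a
banded covariate that reproduces the labels under rank quartiling.  It is
the harness for parameter recovery: at n = 1,000, σ = 0.5 and 200
replicates, each βk's mean estimate falls within 3 Monte-Carlo SEs of truth
and 95% CI coverage stays within [0.92, 0.98].

## Problem sizes and reproducibility

The default region (100 tracts, ~600 blocks, ~450 network nodes, 90
pharmacies) runs the full pipeline in about a quarter of a second, which
makes 20-replicate direction checks and 200-replicate recovery studies
routine; these sizes are the package's chosen simulation scale and are
recorded in each output's provenance header together with the seed, config
hash and package version.  Under the default conditions the end-to-end
negative poverty-Q4 direction appears in ≈96% of seeds.  The pipeline
stages communicate only via documented CSV schemas, so any stage can be
replaced by real data — including a tract table with a pre-computed PWMSD
column, which feeds the statistical stage directly.

## Known limitations

* Distances assume an undirected network: no one-way streets, turn
  restrictions or travel times.
* Coordinates must arrive in a planar km frame; geographic data must be
  projected upstream (the core does no geodesy).
* The GLM quantifies associations across quartiles; it is ecological and
  unadjusted by design (population density being the one optional
  adjustment), not a causal model.
* Spatial autocorrelation of residuals is not modelled; the sandwich SEs
  guard against heteroskedasticity, not against spatial dependence.
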