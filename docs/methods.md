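# Methods

This note documents the models and procedures nichekit implements, the
defaults it ships, the numerical choices behind them, and what the synthetic
test harness does and does not demonstrate.

## Grids, areas and conventions

All layers live on a regular lon/lat grid with square cells (degrees).
Arrays are stored row 0 = north, indexed (row, col), 0-based; coordinates
refer to cell centers, and cell membership uses half-open intervals
[west, east) × [south, north) so boundary points belong to exactly one cell.
Two grids are "aligned" iff all five geometry fields agree within 1e-9
degrees; every multi-raster operation rejects unaligned inputs rather than
resampling silently. The exchange format is the ESRI ASCII grid; both the
`xllcorner` and `xllcenter` header dialects are read (centers converted to
corners), and the default no-data sentinel is −9999 compared by exact
equality. No-data cells are excluded from every sum, mean, classification
and area computation.

Cell areas are geodesic on a sphere of radius R = 6371.0088 km:
area = R²·Δλ·(sin φ_N − sin φ_S). At the extents this package targets the
difference from an equal-area projection is negligible, and the choice keeps
the artifact free of any projection machinery. Areas are reported in
10⁴ km²; great-circle distances use the haversine formula with the same R.

## Spatial thinning

Thinning keeps at most one record per cell — per (species, cell) at species
level, per cell ignoring labels at genus level. The survivor is the first
record in input order: the source is silent on the tie rule, and
first-in-order is deterministic and auditable. Thinning is idempotent, and
input order can only change *which* record survives, never *how many*.

## Variable screening

Layer values are sampled at occurrence points by nearest-cell lookup (the
value of the containing cell). Screening proceeds in two steps: variables
with zero model contribution are dropped, then correlated pairs with
|Pearson r| ≥ 0.80 are resolved greedily in descending |r| (ties by name):
the lower-contribution member is removed unless it is in an explicit `keep`
set, in which case its partner is removed instead (a pair with both members
kept survives). Greedy pairwise elimination — rather than clique analysis —
is standard practice and reproducible; dropping the lower contribution
matches the usual retention of ecologically important, high-contribution
variables. When contributions come from replicated preliminary runs they
are combined by arithmetic mean.

## Maximum-entropy model

The model is the presence/background Gibbs formulation: raw(z) =
exp(λ·f(z))/Z with Z normalizing over the background sample. Feature
transforms operate on min-max-scaled variables L ∈ [0,1] (scaled on the
background; projection values outside the background range are clipped):
Q = L², P = products of distinct L pairs, forward/reverse hinges at evenly
spaced knots rescaled to [0,1], and step indicators at interior knots.
A constant variable keeps a zero L column but contributes no Q/P/H/T.
Hinge/threshold knots default to 20 per variable per direction for
projection-quality fits; the bundled pipeline and tests use 4–5 knots,
which is ample at desk scale.

Fitting maximizes gain = mean_presence(λ·f) − ln E_background[exp(λ·f)] −
Σ β_j|λ_j| by cyclic coordinate-wise proximal descent: each coordinate takes
a soft-thresholded Newton step (curvature from the current Gibbs variance of
that feature, floored at 1e-10) and is backtracked by halving until the gain
does not decrease, so the gain is non-decreasing by construction.
Convergence is a full sweep improving the gain by < 1e-6; the sweep cap is
500 (200 inside the tuning loop), with a warning and the last iterate on
non-convergence. Penalties are β_j = RM · base(class, m) · sd_j(presence)/√m
with the conventional base tables (linear/quadratic/product interpolated on
{(10, 1.0), (30, 0.2), (100, 0.05)}; hinge 0.5; threshold interpolated on
{(10, 2), (100, 1)}), configurable per call. The presence sd inside β is
floored at 1e-3: a feature constant among presences would otherwise be
unpenalized and could diverge on separable data.

The background is all valid cells up to 10,000, else a seeded sample of
10,000 without replacement. The logistic output uses c = exp(H), H the
entropy of the raw distribution over the background, which makes the
all-zero model score exactly 0.5 everywhere — the property the 0.1/0.3/0.5
classification cuts presuppose.

AICc uses k = number of nonzero coefficients and the raw density
renormalized over all cells: AICc = 2k − 2lnL + 2k(k+1)/(n−k−1), flagged
invalid when k ≥ n−1. Tuning evaluates the full RM × FC grid (default
8 × 6 = 48 candidates) and selects ΔAICc = 0, breaking ties by higher test
AUC, then fewer parameters, then lexicographic feature combination. AUC is
the rank-based Mann–Whitney statistic with ties counted 0.5, labelled poor
(≤ 0.7), moderate (≤ 0.9) or high (> 0.9).

Percent contributions credit each accepted coordinate update's gain
increment to the feature's underlying variable (products split 50/50),
clip at zero and normalize to 100. Jackknife importance refits with only /
without each variable at the selected RM/FC. Replicate schemes follow
sample size: genus-level models use subsampling with a 25% test split;
species-level models use 30% (n ≥ 50), 40% (20 ≤ n < 50) or bootstrap with
no held-out test (n < 15); 15 ≤ n < 20 is not covered by the published
scheme and maps to the 40% split with a warning rather than a silent guess.
Replicate surfaces are averaged cell-wise; AUC is averaged over replicates.

## Niche overlap

One PCA (z-scored variables, two components, deterministic sign convention:
the largest-magnitude loading of each component is positive) is fitted on
the pooled occurrence points of all species, so every species shares one
environmental space; a background-calibrated PCA can be supplied by
extracting at background cells instead. Each species' scores are smoothed
onto a shared 35 × 35 grid spanning the pooled score range plus a 10% margin
(so disjoint clouds both fall on-grid), using a product-Gaussian kernel with
per-axis normal-reference bandwidths h = σ·n^(−1/6), floored at 1% of the
extent on a zero-variance axis; densities are renormalized to sum to 1.
Schoener's D = 1 − ½ Σ|p_i − q_i| then compares any two species; it is
symmetric, lies in [0,1], and equals 1/1225 for a uniform surface against a
point mass. Densities are *not* corrected for background availability —
an optional refinement deliberately left out of the default because the
analysis this package follows does not apply one. A per-variable 1-D mode
(`mode="gradient"`, D aggregated by the maximum over variables) is provided
as an alternative reading of "overlap along environmental gradients";
neither mode is asserted to be canonical.

Genus-vs-species geographic consistency uses the cell-wise maximum
composite of species maps, Pearson r over jointly valid cells, and the
Jaccard overlap ratio 100·area(both ≥ 0.5)/area(either ≥ 0.5).

## Classification and change indicators

Suitability classes are unsuitable (p < 0.1), poor (0.1 ≤ p < 0.3),
moderate (0.3 ≤ p < 0.5) and high (0.5 ≤ p ≤ 1.0) — lower bounds inclusive,
upper exclusive, high closed at 1. "Suitable" for the change accounting is
binary, p ≥ 0.1: the union of the three suitable classes. This binary
reading (rather than same-class persistence) is the one under which
stability indices in the high-90s coexist with visible class-level
degradation flows, which the 4 × 4 flow matrix records separately.

For a transition, A_expansion is area unsuitable→suitable, A_contraction
suitable→unsuitable, A_stable suitable→suitable; A_final = A_initial +
A_expansion − A_contraction holds exactly, and flow-matrix marginals
reconcile with per-period class areas. Indicators: RCR, CI, SI as
percentages of A_initial and SDR = min/total turnover, defined 0 when there
is no turnover. Percentages are rounded half-away-from-zero to 2 decimals,
and period means average the *rounded* per-transition values — the
convention verified to match published summary rows of this kind.

## Centroids, rank test, gap analysis

The centroid of the high class is the area-weighted mean of cell-center
coordinates over the binary high mask (suitability-weighting is not used:
the quantity is the geometric center of the extracted area). Longitude is
averaged arithmetically; supported extents never span the antimeridian.
Per-scenario migration distances are the consecutive-period displacements
(current→2050s→2070s→2090s, n = 3 per scenario), compared across scenarios
by the Kruskal–Wallis test with mid-ranks, the tie-correction factor
1 − Σ(t³−t)/(N³−N), and a chi-square reference with df = groups − 1. At
n = 3 per group the chi-square reference is an approximation; the test
suite bounds its deviation from an exact permutation null.

Gap analysis designates moderate + high cells as the priority conservation
area. A priority cell counts as covered iff its center lies inside a
protected polygon — a deliberate cell-center rule whose error is bounded by
one ring of boundary cells, in exchange for determinism and simplicity over
fractional-cell overlay.

## Synthetic-data generator

The generator provides ground truth for every stage at a desk-scale default
grid of 100 × 120 cells at 0.05° (≈ 5 km, the working resolution of gridded
bioclimate data). Environmental layers are low-pass-filtered white noise
(Gaussian kernel, σ = 5 cells) — smooth enough to resemble interpolated
climate surfaces, and simple enough that requested pairwise correlations can
be imposed *exactly* by empirical orthogonalization (variogram-based
simulation would add realism the tests do not need). Occurrences are drawn
with cell probability proportional to a known inverse-logit linear-quadratic
suitability; a configurable fraction are re-draws inside already-occupied
cells with sub-cell jitter, so grid thinning (not coordinate deduplication)
is what removes them. Scenario surfaces flip exactly the planned number of
frontier cells across the 0.1 boundary per period, making every transition
area known by construction. Two-species niche clouds are unit-SD bivariate
normals a configurable number of pooled SDs apart on gradient layers, so
niche overlap is controllable from identical (D → 1) to disjoint (D → 0).
Protected polygons are unions of whole priority cells added in seeded random
order until a coverage target is met, so realized coverage is within one
cell-area of the target. Every generator is a pure function of its seed.

What passing tests therefore show: the *operations* are correct — thinning
counts, correlation filtering, optimizer invariants, parameter and
response-peak recovery, overlap closed forms, exact transition accounting,
rank statistics, coverage arithmetic. What they do not show: behaviour
under real bioclim covariance structure, spatial sampling bias, georeferencing
error, or projection transfer — properties of data, not of the code paths
exercised here.

## Problem sizes used in the test and acceptance runs

The bundled runs use grids of 20 × 30 to 100 × 120 cells, backgrounds of
1,000 cells, presence samples of 60–2,000, tuning with 2 variables and 4–5
hinge knots over the full 48-candidate grid, and 10⁵-permutation null
distributions for the rank test — sizes chosen so the whole suite settles
in well under a minute while every statistic is estimated tightly enough
for its stated tolerance.

## Known limitations

- No reprojection or resampling: all inputs must share one grid.
- No categorical features, cloglog output, clamping flags or MESS-style
  extrapolation diagnostics in the maximum-entropy model.
- GeoTIFF and Shapefile I/O are not included; ESRI ASCII and GeoJSON are
  the supported formats.
- Niche-equivalency/similarity permutation tests are out of scope.
- The coordinate optimizer warns rather than fails on hitting the sweep
  cap; heavily hinged models on large backgrounds may need the cap raised.
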