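# nichekit

Ecological niche modelling and habitat-dynamics analysis for species
distribution studies, built for biogeographers and conservation planners who
work with presence-only occurrence records and gridded environmental layers
(bioclimate, terrain, soil, UV radiation).

The package implements a complete, testable pipeline:

1. **Spatial thinning** of occurrence records to one point per grid cell
   (genus- or species-level), the standard guard against clustered herbarium
   sampling.
2. **Variable screening**: extraction of layer values at occurrence points,
   removal of zero-contribution variables, and greedy elimination of highly
   correlated pairs (|Pearson r| ≥ 0.80) with an ecological-importance
   override.
3. A **maximum-entropy suitability model** written from scratch: over
   background cells the species' distribution is the Gibbs density

   raw(z) = exp(λ·f(z)) / Z,

   where f(z) are bounded feature transforms (linear L, quadratic Q, product
   P, hinge H, threshold T) of the environmental variables. Coefficients λ
   maximize the L1-regularized training gain by coordinate-wise proximal
   descent; per-feature penalties are β_j = RM · base(class, m) · sd_j/√m.
   The logistic output rescales raw with c = exp(H) (H = entropy of the raw
   distribution) so an uninformative model scores exactly 0.5.
4. **Model selection** over the RM × FC grid (RM 0.5–4 in steps of 0.5; FC ∈
   {L, H, LQ, LQH, LQPH, LQPHT}, 48 candidates) by small-sample-corrected
   AICc, choosing ΔAICc = 0, plus rank-based AUC evaluation, jackknife
   variable importance, response curves and percent contributions.
5. **Niche overlap**: occurrence environments projected into a shared PCA
   space, per-species kernel densities on a common 35 × 35 grid, and
   Schoener's D = 1 − ½ Σ|p_x,i − p_y,i| for every species pair.
6. **Habitat dynamics**: suitability classified into unsuitable / poor /
   moderate / high at 0.1 / 0.3 / 0.5, geodesic transition areas between
   periods, and the indicator set
   RCR = (A_final − A_initial)/A_initial × 100,
   CI = (A_exp + A_con)/A_initial × 100, SI = A_stable/A_initial × 100,
   SDR = min(A_exp, A_con)/(A_exp + A_con) ∈ [0, 0.5].
7. **Centroid migration** of high-suitability habitat (area-weighted,
   haversine distances) with Kruskal–Wallis comparison across emission
   scenarios, and **protected-area gap analysis** of the moderate + high
   priority area.
8. A seeded **synthetic-data generator** that produces aligned raster
   stacks with controlled inter-variable correlations, occurrence samples
   from a known suitability truth (with within-cell duplicates), multi-period
   scenario surfaces with exactly planned expansion/contraction, two-species
   niche clouds of controllable separation, and protected-area polygons of
   known coverage — so every stage is tested against ground truth without
   downloading any real data.

Rasters are exchanged as ESRI ASCII grids (`.asc`), occurrences as CSV
(`species,lon,lat[,elevation,source]`), protected areas as GeoJSON.

## Worked example

```python
from nichekit import synth
from nichekit.dynamics import classify, transition_summary, indicators
from nichekit.occurrences import thin_occurrences

spec = synth.DEFAULT_SPEC                      # 100 x 120 cells, 0.05 deg
stack = synth.make_env_stack(1, spec, n_vars=4, corr_pairs=[(0, 1, 0.9)])
truth = synth.TruthModel({"Bio1": (1.5, -1.0), "Bio3": (1.0, 0.0)})
occ = synth.sample_occurrences(truth, stack, 300, duplicate_rate=0.3, seed=1)
thinned = thin_occurrences(occ, spec, level="genus")
print(f"records: {len(occ)} raw -> {len(thinned)} after thinning")

base = truth.suitability(stack)
ss = synth.make_scenario_set(base, {("SSP585", "2050s"): (40, 5)}, seed=1)
ts = transition_summary(classify(ss.rasters[("SSP585", "current")]),
                        classify(ss.rasters[("SSP585", "2050s")]))
ind = indicators(ts)
print(f"A_initial={ts.a_initial:.2f}  A_final={ts.a_final:.2f}  "
      f"A_exp={ts.a_expansion:.2f}  A_con={ts.a_contraction:.2f} (10^4 km^2)")
print(f"RCR={ind.rcr}%  CI={ind.ci}%  SI={ind.si}%  SDR={ind.sdr}")
```

prints

```
records: 300 raw -> 209 after thinning
A_initial=25.09  A_final=25.19  A_exp=0.11  A_con=0.01 (10^4 km^2)
RCR=0.38%  CI=0.49%  SI=99.95%  SDR=0.11
```

The 300 simulated records occupy 209 distinct 5-km-scale cells, so thinning
keeps exactly one per cell.  The scenario constructor flipped 40 frontier
cells to suitable and 5 to unsuitable; the transition accounting recovers
those areas exactly, and the indicators read them as a mild net expansion
(RCR 0.38%) of a very stable system (SI 99.95%) with low, one-sided turnover
(SDR 0.11).

A full config-driven run (simulate → thin → select → tune → fit → predict →
overlap → classify → dynamics → centroid → gap) is available as
`nichekit report --seed 1 --outdir run/`, and each stage as its own
subcommand (`nichekit thin --grid ref.asc --level genus in.csv out.csv`,
`nichekit overlap …`, `nichekit gap …`; see `nichekit --help`).

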