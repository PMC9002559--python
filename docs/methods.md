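# Methods

This note documents the models and procedures implemented in `invasipath`,
the assumptions behind them, the tunable parameters and their defaults, and
the design choices made where the design was genuinely open.

## Scope and data model

All gridded quantities travel as `RasterLayer`: a north-up square-celled
grid on a single projected CRS in meters, world coordinates at cell
centers, NaN for nodata.  Rasters serialize to ESRI ASCII grids (plain
text), points and polylines to CSV/GeoJSON.  Reprojection between CRSs is
out of scope; all inputs are assumed co-registered, and `EnvStack` rejects
layers whose geometry differs from the shared grid.

## Synthetic landscapes

The generator exists because the pipeline's intended inputs — national
climate, soil, land-use, and hydrography rasters — are not shippable with a
package, and because measured ground truth is the only way to test
parameter recovery.  A `SyntheticScenario` is a pure function of its seed:
every stage draws from a namespaced `SeedSequence` stream, so identical
scenarios are bit-identical.

**Terrain.**  The DEM is spatially autocorrelated noise (white noise
smoothed by a Gaussian kernel, `smoothing_cells` = 6 cells) scaled to
`relief_m` = 600 m, then depression-filled by priority flooding.  The fill
guarantees every cell has a monotone non-increasing downhill path to the
boundary, which makes the synthetic rivers — steepest-descent traces from
each basin's highest cell, restricted to their basin — physically coherent.
Catchments grow from `n_basins` low, mutually separated boundary outlets by
priority-flood watershed labeling (elevation order, ties to the lowest
basin index), partitioning the grid into contiguous basins with one river
each.  Slope is the finite-difference gradient magnitude in degrees.
Roads are straight random transects; lakes small disks at low elevations.

**Predictors.**  Thirteen layers with the abbreviations conventional in
this literature.  Bio6 (minimum temperature of the coldest month, 0.1 °C),
Bio12 (annual precipitation, mm) and SolarRad (W/m²) are affine in the DEM
— a lapse-rate analogue — plus autocorrelated noise scaled by `noise_sd`
(default 0.5); with `noise_sd = 0`, Bio6 is a strictly monotone transform
of −DEM.  DistWaterc, DistLakes and DistRoadsRailw are DEM-corrected
surface distances to the terrain features.  HII (human-impact index) and
TreeDens (% canopy) are bounded autocorrelated fields clipped to [14, 56]
and [0, 100].  LUType, SoilClass, SoilText and SoilStruct are nearest-seed
(Voronoi) mosaics with 6/5/4/4 classes.

**Truth and occurrences.**  True suitability is logistic:
p = expit(β₀ + Σ βⱼ zⱼ) over z-scored continuous predictors.  The default
coefficients — Bio6 +6, DistWaterc −5, Bio12 +3, HII +2, TreeDens −1.6,
intercept −4 — encode a warmth-loving, river-bound, disturbance-tolerant
invader.  Their magnitudes were chosen so that fitted single-algorithm AUCs
fall in the 0.75–0.93 band characteristic of well-determined riparian-
invader SDMs (an earlier, weaker draft produced landscapes on which no
algorithm could clear the 0.75 AUC gate, i.e. a study system materially
harder than the one this package emulates).  Presences (default 59, the
field + literature sample size typical of a national survey of a recent
invader; 100 m cells) are drawn without replacement with probability
proportional to true suitability and placed at cell centers.

**What the generator does not emulate:** spatial sampling bias (roadside
survey effort), positional error in occurrences, interactions or
non-monotone responses in the truth, temporal climate variation, and real
hydrographic topology.  Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the stated generating model,
not performance guarantees on real survey data.

## Predictor preparation

**Resampling** is bilinear for continuous layers and nearest-neighbor for
categorical ones (which therefore cannot invent class codes).  Cells whose
bilinear stencil touches nodata become nodata; disjoint extents are an
error.

**Surface distance** treats the grid as an 8-connected graph with edge
length √(planar² + Δz²), planar = cell size (cardinal) or cell size·√2
(diagonal), and runs multi-source Dijkstra from the feature cells.  Nodata
is impassable.  This is the Pythagorean path-distance interpretation of
"DEM-corrected distance"; it equals planar octile distance on flat terrain
and is verified against an independent brute-force shortest-path oracle.

**VIF elimination** is iterative: compute VIF_j = 1/(1−R²_j) for every
continuous variable (R² from regressing j on the other continuous
variables over complete-case cells, deterministically subsampled to at
most 10,000), drop the single worst variable while any VIF exceeds the
threshold (default 10), recompute.  Single-pass elimination can leave
survivors above the threshold; iteration cannot, and it is idempotent.
Perfect collinearity yields VIF = +inf and immediate elimination rather
than a crash.  Categorical layers pass through untouched — how categorical
predictors should enter a VIF screen is genuinely ambiguous, and excluding
them is the conservative reading.  The elimination order is logged.

## Ensemble SDM

**Sampling design.**  10,000 pseudo-absences (the convention for
background-point SDMs) drawn uniformly over non-nodata cells, excluding
presence cells; presences deduplicated per cell.  On synthetic grids
smaller than 10,000 eligible cells the pipeline caps the draw at the
available background (logged; `cap_pseudo_to_available`).

**Splits.**  Stratified by class; per class, floor(0.75·n) rows calibrate
and the rest validate (59 presences → 44/15).  Each of the default 10
repetitions draws a fresh split shared by all algorithms, so pooled
ensemble scores are comparable across algorithms.

**Algorithms.**  Eight learners behind one preprocessing contract:
tree-based learners (CTA = decision tree, GBM = gradient boosting,
RF = random forest) consume raw categorical codes; all others get one-hot
categoricals and standardized continuous inputs.  MAXENT is realized as an
L1-penalized logistic presence/background model — the standard
approximation when the Java implementation is unavailable, and close to it
for linear features.  MARS is a hinge-basis (max(0, x−t), max(0, t−x) at
quartile knots) logistic regression, an adaptive-spline approximation
without the forward/backward basis search.  GAM is a cubic-spline-basis
(5 knots) logistic regression.  GLM and ANN wrap plain logistic regression
and a single-hidden-layer perceptron (16 units).  Class imbalance is
handled by balanced weights wherever the learner accepts them.

**Evaluation.**  AUC is the full-ranking trapezoidal ROC area (equivalent
to pair concordance, and tested against an O(n²) oracle).  The binary
threshold maximizes TSS over every distinct score; ties go to the lowest
qualifying threshold (maximizing sensitivity), deterministically.
Sensitivity, specificity, TSS and omission rate are reported at that
threshold; TSS = sens + spec − 1 and omission = 1 − sens hold by
construction.

**Gating and combination.**  An algorithm is retained iff its replicate-
mean AUC strictly exceeds the gate (default 0.75).  Retained algorithms'
replicate-mean probability surfaces are combined with AUC-proportional
weights (configurable to uniform); replicate aggregation into one map per
algorithm mirrors reporting one row per algorithm.  Ensemble metrics and
the final threshold come from pooled held-out predictions of the weighted
ensemble across replicates — one declared choice among several defensible
definitions of "ensemble performance".  If nothing passes the gate the fit
aborts with every AUC listed; that is a finding, not a bug.

**Contributions.**  For each variable, each retained algorithm is refitted
without it (full training table, fixed seed); the score is
max(0, 1 − r) with r the Pearson correlation between full and omitted
predictions over a deterministic sample of up to 2,000 valid cells,
averaged over retained algorithms and normalized to 100 %.  A variable
whose omission changes nothing contributes exactly 0.  Refit failures are
flagged, warned about, and excluded from normalization.

## Cores, connectivity, risk

**Cores.**  Connected regions of the binary map (8-connectivity by
default, configurable to 4) with area ≥ `min_core_area_km2` (default
1 km²; "smaller than" is read strictly, so a patch of exactly 100 cells at
100 m survives).  Patch ids follow row-major order of each patch's first
cell, making outputs deterministic.  A core is confirmed iff an occurrence
point falls inside it (point-in-patch; no buffer).

**Resistance and corridors.**  Resistance = max(1 − p, ε), ε = 10⁻³ so
perfect habitat is cheap but never free.  Cost distance uses edge cost
(r_i + r_j)/2 × step length — the standard GIS convention — with core
cells as zero-cost entry points.  Candidate core pairs come from
cost-allocation adjacency: every cell is allocated to its cheapest core
(ties to the lowest id), and pairs whose regions share a rook edge are
linked; a minimum spanning set over pairwise LCP costs then guarantees a
connected corridor graph on any fully passable surface.  This neighbor
rule produces on the order of one to two corridors per core, as corridor-
mapping practice expects, rather than the quadratic all-pairs set.  Each
corridor carries its backlink-traced LCP (consecutive cells are
8-neighbors), accumulated cost, and geometric length (Σ steps / 1000 km).
The permeability surface for a pair is cost_a + cost_b − lcp_cost (0 on
the LCP); the mosaicked minimum over linked pairs is cut off by default at
10 × cell size × mean resistance.

**Risk.**  Catchments are counted under the single-cell LCP trace (not the
swath — configurable in principle, the trace is the declared reading).
The rule is exhaustive and mutually exclusive over n ≥ 1: n = 1 high,
2 ≤ n ≤ 5 medium, n ≥ 6 low.  Summaries report per-class count, total,
mean (= total/count), max, min length and confirmed-core contact; means
are additionally rounded to integer km for presentation, raw values always
retained.

## Numerical and reproducibility notes

- One top-level seed; every stage consumes a namespaced `SeedSequence`
  stream, so pipeline outputs (CSV included) are byte-identical across
  reruns with the same config.
- Dijkstra runs on a sparse CSR graph over valid cells only; unreachable
  cells get +inf (distinct from nodata's NaN).
- Threshold ties, allocation ties, watershed ties, and patch ordering are
  all broken deterministically (lowest threshold / lowest id / first in
  row-major order).
- The acceptance script and the heavier tests run the scenario at
  60×80–100×120 cells with 200 presences, 2,000 pseudo-absences and 2
  replicates — the package's demonstration scale; the survey-scale defaults
  (10,000 pseudo-absences, 10 replicates) remain the configured defaults
  for real-data use.

## Known limitations

- MAXENT/MARS/GAM are principled approximations, not the reference
  implementations; coefficients are not interchangeable with theirs.
- No spatial cross-validation: a single random split repeated, as in the
  workflow this package operationalizes.  With spatially autocorrelated
  data this optimistically biases AUC.
- Corridor topology depends on the allocation-adjacency rule; tools with
  different neighbor rules will link different (though heavily
  overlapping) pairs.
- The VIF screen ignores categorical predictors entirely.
- No reprojection, no CRS awareness beyond "meters on one grid".
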