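# Methods

## Scope and model

`urbanheat` screens a fixed set of cities — each a morphological urban
polygon with a name and continent — against mean-annual-temperature (MAT)
thresholds derived from the human-climate-niche literature, and relates
threshold exceedance to intra-urban morphology (Local Climate Zones, LCZ)
and to economic capacity (gridded GDP PPP).  The analysis is deliberately
static and descriptive: no climate, demographic or land-use modelling
happens inside the package; all dynamics enter through the input rasters.

The processing chain is: zonal aggregation → niche screening → morphology
comparison → adaptation scoring → capacity overlay.  Each stage is a pure
function of its tabular/raster inputs, so the pipeline is deterministic for
a fixed input set and seed.

## Zonal statistics and the inclusion rule

A raster cell belongs to a city iff its **center** lies inside the city
polygon, with centers exactly on an edge counting as inside.  The
alternative (area-weighted intersection) was rejected because center
assignment guarantees each cell contributes to at most one city in a
non-overlapping boundary set, so population and GDP sums never
double-count.  This is a package convention, not a property of any
upstream dataset; it is documented and tested (edge-tie tests included).

MAT uses an unweighted arithmetic cell mean.  On ~1 km geographic grids the
cos-latitude area variation across a single city is far below the climate
data's own uncertainty; a cos-latitude weighted mode exists
(`zonal_mean(..., weighted=True)`) for sensitivity use.  LCZ shares are
computed over classified cells only — nodata cells shrink the denominator
rather than forming a pseudo-class — and are emitted as explicit zeros for
all 17 codes.  Grids must share the boundary's CRS identifier; nothing is
ever silently reprojected, and rotated/sheared rasters are rejected at
read time.

## Thresholds, bands and exposure

"Exceeding" a threshold is **strict** (`mat > 29`): the verbal convention
"over 29 degrees" reads most naturally as a strict inequality, and the
same rule is used everywhere (banding, group splitting, capacity
filtering), so a city at exactly 29.000 °C is consistently a non-exceeder.
Bands partition all finite-MAT cities: `below_27`, `27_to_29`
(27 < MAT ≤ 29) and `above_29`.  Exposed population per period uses a
single mapped year (2025 / 2070 / 2100) with no within-period averaging.
ΔMAT is the exact difference against the 1981–2010 reference zonal mean of
the same city.  Continental summaries report medians and quartiles with
linear interpolation between order statistics.

## Welch comparison and diagnostics

LCZ group shares of the < 29 °C and > 29 °C city groups (terminal period,
per scenario) are compared with Welch's two-sample t-test: unbiased
variances, Welch–Satterthwaite degrees of freedom, two-sided p from the
Student-t survival function.  Degenerate inputs are defined exactly: n < 2
in either group yields a missing result (no star); two zero-variance
samples give t = 0, p = 1 when means agree and |t| = ∞, p = 0 otherwise.
Significance is raw p < α (default 0.05) with **no multiple-testing
correction** by default, matching common practice of starring raw
per-panel tests; a Benjamini–Hochberg mode (`correction="bh"`) exists for
sensitivity analyses.  Tests are emitted both pooled over all cities and
stratified by continent; both are reported because either could legitimately
drive an annotation.

The median-position diagnostic compares each exceeder's group share to the
median over **all** cities of its continent (exceeders included).  The
reference population is configurable (`median_population="nonexceeders"`)
because the natural-language phrase "continent-specific median" does not
pin it down; ties count as *not* satisfying the strict comparison, so a
single-city continent contributes a tie by construction.

The default group memberships (compact = {1,2,3}, open = {4,5,6},
green = {A,B,C}, low_plants = {D}, bare_natural = {E,F}, water = {G}, the
remaining built classes singleton) follow standard LCZ semantics; they are
config-overridable since group labels in the source literature are not
accompanied by explicit membership lists.

## Adaptation scoring

The measure × LCZ suitability matrix is binary over columns
LCZ 1, 2, 3, 4, 8, 10 and contains **ten** measure rows; all ten are
implemented even though the accompanying prose speaks of "eight
interventions" — the tabulated matrix is taken as authoritative, and which
two rows that count excludes is unknowable from the text.  LCZ classes
absent from the matrix (5, 6, 7, 9, A–G) carry explicit weight 0, making
the dot product total over all 17 classes.  Scores are therefore bounded in
[0, 1], equal 1 iff the whole classified area lies in weight-1 zones, and
are monotone under share transfer from weight-0 to weight-1 zones.  Scores
are *not* renormalised by built-area fraction: a heavily vegetated city
genuinely has low built-fabric leverage for these measures.  Continental
aggregation is restricted by default to terminal-period exceeders under the
configured reporting scenario (sum = total potential, mean = per-city
potential).

## Capacity overlay

GDP is the 2020 PPP grid summed per city footprint and held fixed for all
periods (no GDP projection), used as a deliberately crude adaptive-capacity
proxy; a per-capita column can be derived downstream but is not used by
default.  The exceeder-filtered summary emits `n = 0` rows for continents
with no qualifying city rather than dropping them.

## The synthetic world

The generator emulates the *structure* the analysis assumes, not the
physics of any real dataset:

* **Geometry** — cities are axis-aligned rectangles (2–4 coarse cells per
  side) on a slot lattice with ≥ 1-cell gaps, snapped to coarse cell
  edges.  This guarantees non-overlap, ≥ 4 coarse centers per city, exact
  nesting of the fine (LCZ) grid, and no centers on polygon edges.  Default
  cell sizes: 0.1° coarse, 0.01° fine (10 × 10 nesting, mirroring the
  ~1 km vs ~100 m ratio of real climate and LCZ products).
* **Climate** — each city has a planted baseline MAT drawn per continent
  (means 10.5–25.5 °C, hot continents near the niche edge) plus a planted
  warming increment per scenario × period (means 0.8–4.0 °C, sd 0.3 °C,
  increasing along SSP1-2.6 → SSP3-7.0 → SSP5-8.5 and through the century).
  Rasters are constant at the planted value inside the footprint (optional
  cell noise, default sd 0).  Planted temperatures are quantized to
  2⁻¹⁰ °C so that cell values, zonal means over equal cells and reference
  deltas are exact dyadic floating-point arithmetic — planted-truth
  recovery tests can assert equality, not approximation.
* **Exceeders** — exactly `n_hot_cities` (default 20 of 120) are planted
  above 29 °C in 2071–2100 under SSP5-8.5 by shifting their baselines
  above the threshold minus their drawn increment (margin 0.2–2.5 °C);
  all others are forced below by a 0.3–4 °C margin.  The 20/120 default
  mirrors a study population where roughly one city in six leaves the
  niche by century's end.
* **Population / GDP** — integer totals (log-normal per mapping year,
  gamma per continent respectively) allocated evenly over the city's
  coarse cells with the remainder on the first cell, so zonal sums recover
  them exactly with no rasterization slack.
* **LCZ** — one Dirichlet share draw per city from a hot or cool regime
  (hot: more bare soil/rock, less vegetation; concentration strength 120),
  realised over the fine cells by deterministic largest-remainder
  allocation.  A multinomial mode exists for stochastic tests.
  `perturb_group_shares` shifts the hot regime's expected share of one
  class while preserving total concentration, for power studies.

What the generator does **not** emulate — spatial autocorrelation of
climate fields, realistic coastlines and city shapes, within-city climate
gradients, scenario-consistent demography — means passing tests certify
the *pipeline arithmetic and contracts*, not the realism of any scientific
conclusion drawn from real rasters.

## Numerical and design choices

* Largest-remainder apportionment breaks remainder ties by lower class
  index, deterministically.
* All generator randomness flows from one seeded `numpy` generator in a
  fixed documented draw order; same config ⇒ bit-identical rasters, truth
  table and downstream CSVs (verified byte-for-byte in tests).
* GeoTIFF I/O writes north-up scale/tiepoint georeferencing plus a minimal
  GeoKey directory and a GDAL-style nodata tag; reading rejects anything
  it could misinterpret (rotated transforms, off-origin tiepoints).
* ESRI shapefile input is not supported; boundaries travel as GeoJSON.
* Quartiles everywhere use linear interpolation (`numpy.percentile`
  default).
* Reference problem sizes: the shipped study configuration uses 120 cities
  with 20 planted exceeders on a 56 × 56 coarse / 560 × 560 fine grid, and
  the Welch calibration/power checks use 100 replicate worlds of 50 cities
  (25 per temperature group, Dirichlet strength 55 ⇒ group-share sd ≈ 4
  percentage points, planted bare-surface effect +8 points).

## Known limitations

* The cell-center rule makes very small polygons (no cell center inside)
  legitimately empty; such cities are flagged, logged, listed in the run
  manifest, and excluded from downstream tables — never silently dropped.
* Welch's t on share data near 0 or 1 is approximate (shares are bounded);
  the calibration test shows the rejection rate stays within the binomial
  band at the sizes used, but heavily skewed small-sample strata should be
  read with care.
* GDP totals as capacity ignore institutional strength, governance and
  within-city inequality.
* No reprojection, resampling or area-weighted zonal statistics.
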