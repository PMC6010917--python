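# Methods

## Coordinate handling

Raw logger rows store positions in the NMEA GPGLL convention: whole degrees
concatenated with decimal minutes plus a hemisphere letter (`4916.46,N` =
49° 16.46′ N = 49.2743333°). The inverse encoder writes four decimal-minute
digits, so a decode–encode round trip is exact to better than 1 × 10⁻⁶
degrees. Analyses use two planar/metric layers:

* **Projection** — UTM Zone 13N on NAD83 (GRS80 ellipsoid), implemented as
  the 6th-order Krüger transverse-Mercator series. Round-trip error is
  below 10⁻¹³ degrees, and the forward map agrees with an independent
  Snyder-series implementation to < 5 mm across the zone.
* **Geodesics** — Vincenty's inverse formula on WGS84, matching R
  `geosphere::distGeo` to < 10⁻⁵ m at pasture scale (frozen oracle values
  in the test suite). NAD83 vs WGS84 is irrelevant at these separations;
  both datums are kept explicit because projection and distance follow
  different conventions in the field workflow this package supports.

Per-minute herd dispersion deliberately uses planar UTM distance (the
distance-matrix convention for this analysis), daily travel distance uses
ellipsoidal geodesics; at sub-kilometre scale the two agree within 0.1%,
with the residual difference dominated by the UTM scale factor (up to
~0.45% far from the central meridian — visible only in bench tests placed
outside the zone's core).

## Cleaning rules

1. **Duplicates**: rows identical in all fields (stale data from a
   previous deployment left on the card) are reduced to the first
   occurrence.
2. **Cropping**: a fix is kept only if the assigned pasture polygon covers
   it; discards are counted as *wrong-pasture* (inside another pasture —
   fence-line GPS jitter or a true fence crossing) or *out-of-bounds*
   (transport legs, gross outliers). An optional fence buffer (default
   0 m) can tolerate jitter near shared fences.
3. **Daytime window**: local time in the half-open interval
   [04:00, 22:00). The boundary convention is a package choice; the window
   and the UTC offset (default −6 h) are configurable.
4. **Deployment validity**: ≥ 1,000 retained fixes. Invalid deployments
   remain in QC reports but are excluded from analysis.

Counts removed per reason always sum to input minus output, and the
pipeline is idempotent on its own output; both are asserted in tests.

## Geolocation QC

CEP95 is the 95% empirical quantile (numpy's linear interpolation between
order statistics by default; configurable) of geodesic distances from each
fix to a reference — the unit's own centroid for precision, a surveyed
point for accuracy. The centroid is the arithmetic mean of decimal-degree
coordinates, adequate at bench scale. Under isotropic per-axis Gaussian
error σ the radial error is Rayleigh, so CEP95 = σ√(−2 ln 0.05) ≈ 2.4477 σ;
σ = 1.634 m gives 4.0 m and σ = 0.735 m gives 1.8 m, which is how the
estimator is calibrated end-to-end. Across-unit summaries report mean ±
SE (sample SD / √units).

## Logging schemes

Windows are clock-aligned (floor to the window width, which must divide
60 min), matching how timestamps are re-binned in practice. Regular
logging keeps the first fix per window; burst logging keeps all fixes in
the first 5 or 10 minutes of each hour (phase configurable). Both are
strict subsequences of the input, so every derived distance is bounded by
the constant-logging value. Battery projection is plain arithmetic
(`hours = base × factor`, days floored); the two published figures for the
5-min burst pattern (171 h × 7.5 = 1,282.5 h vs the printed 1,306 h ≈ 54
days) are both surfaced rather than reconciled.

## Synthetic herd model

The generator provides ground truth for every estimator. Its structure:

* **Centroid**: correlated random walk at the fine step Δt (default 1 s) —
  heading increments N(0, 0.2²·Δt rad), speed = 0.07 m/s × a diel
  multiplier (0.1 for 22:00–04:00, 1.5 for the 05:00–09:00 and 16:00–20:00
  grazing peaks, 0.7 otherwise). The schedule reproduces the familiar
  bimodal grazing-activity profile; the speed level yields daily travel of
  a few kilometres, typical of pastured cattle and sheep.
* **Animals**: independent per-axis Ornstein–Uhlenbeck excursions about
  the centroid, discretized exactly as a stationary AR(1):
  D_{k+1} = a·D_k + s√(1−a²)·Z, a = exp(−λΔt), with spread s = 20 m and
  relaxation rate λ = 2 × 10⁻⁴ s⁻¹ (correlation time ≈ 83 min). The
  stationary pairwise distance between herd-mates is then Rayleigh with
  mean s√π ≈ 35.4 m — between published sheep (~42 m) and cattle (~76 m)
  herd-mate distances — and the 20-s excursion jitter stays small relative
  to progressive travel. λ and s are the two cohesion dials; the closed
  form makes them directly testable.
* **Boundary**: reflecting fold at the pasture fence (800 × 800 m square
  by default), keeping every true position inside the polygon. Reflection
  slightly perturbs the OU stationary law near the fence; with s ≪
  pasture side the effect is negligible.
* **Observation model**: one candidate fix per 20 s, independent isotropic
  per-axis Gaussian error (σ = 1.634 m ⇒ CEP95 = 4.0 m), Bernoulli fix
  failures (default 2%), rare 500-m outliers (default 5 × 10⁻⁴). The
  pasture anchor is a WGS84 point inside UTM Zone 13N, so planar metres
  and geographic coordinates interconvert exactly through the projection.
* **Randomness**: seeds are split per purpose and per animal
  (`SeedSequence([seed, k])`), so runs are bit-reproducible and adding an
  animal never changes existing paths.

What the generator does **not** emulate: temporally autocorrelated GPS
error (real receiver error drifts over minutes; independent noise inflates
the constant-logging path length and therefore the correction factors β
well above the ~1.2–2 seen with field collars), behavioural state
switching, terrain or forage heterogeneity, and collar-to-collar
performance differences. Passing tests therefore demonstrate estimator
correctness and calibration on a known movement law, not field-identical
effect sizes. Two further idealizations worth noting: Gaussian OU
increments are unbounded, so no hard per-step speed cap exists; and
fine-step path length is discretization-dependent (OU paths roughen as
Δt → 0), which is why ground-truth distances are always quoted at a stated
fine step.

## Correction-factor study

Daily distance sums geodesics between consecutive daytime fixes within a
local date; grouping by date automatically excludes the overnight gap.
Days with fewer than 12 fix-bearing daytime hours can be dropped before
regression (ragged trial edges).

The correction model is `constant = β · estimated` with Gaussian errors,
fitted by maximum likelihood (closed form β = Σxy/Σx²; Wald CI from the
observed information; profile-likelihood and intercept options provided —
through-origin is the default because the correction is applied by pure
multiplication). Validation applies β to a held-out trial and refits the
slope of constant on corrected-estimated.

Two calibration choices in the validation interval deserve explanation,
because the naive refit CI badly under-covers:

1. **The herd, not the animal, is the independent unit.** Herd-mates share
   the herd path, so their daily distances (and daily
   estimated-vs-constant ratios) are strongly correlated; treating
   animal-days as independent makes intervals several times too narrow.
   The study aggregates animal-days to herd-day means before regression.
2. **Training uncertainty propagates.** The corrected slope differs from 1
   through both the holdout sampling error *and* the error in β̂; the CI
   therefore adds the relative training variance of β̂ to the refit
   variance, and uses a Student-t quantile (df = holdout days − 1) rather
   than a normal one at the small day counts of short trials.

With both in place, replicate simulated studies show the event "all four
schemes' corrected-slope CIs contain 1" in ≈ 96% of runs; with the naive
interval the rate is a fraction of that. The plain refit interval remains
available (`propagate_training=False, small_sample=False`).

The default study conditions mirror a field season at reduced scale: four
monthly trials, two independent herds per month, three collars per herd,
five-day trials, and a 5-s fine step for the movement simulation (the
fine step only needs to resolve the 20-s fix cadence).

## Patch occupancy

Grids are anchored at the pasture bounding-box minimum corner, cells
ordered row-major: 2 × 2 quarters (~16 ha for the 800-m square) and
100 × 100 m cells (exactly 64 × 1 ha for the square; edge cells clipped
for irregular pastures). Cell membership is half-open
[x₀, x₀+w) × [y₀, y₀+h), with the outer max edges closed, so every fix
lands in exactly one cell deterministically. Occupancy comparisons are
per deployment (per datalogger), then averaged across deployments;
pooling animals first is available as an option. Note that a coarse
cell's signed difference is the sum of its nested fine-cell differences —
cancellation means the coarse maximum can exceed *or* fall below the fine
maximum, so the two levels are reported separately rather than ordered.

## Numerical and degenerate-input conventions

* Quantiles: numpy linear interpolation unless configured otherwise.
* Ties in subsampling windows: broken by input (file) order.
* Zero fixes: occupancy and CEP estimators raise; daily distance with a
  single fix reports 0 m flagged `few_fixes`.
* Malformed raw rows are skipped and counted, never fatal (loggers
  truncate rows at power loss).
* Vincenty iteration: tolerance 10⁻¹² rad, with a coincident-point
  short-circuit; non-convergence cannot occur at pasture separations.
* All Monte-Carlo assertions in the test suite use batch-means standard
  errors where series are autocorrelated (the OU correlation time spans
  ~83 min of per-minute values).
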