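# Methods

## The procedure

The pipeline treats one *bird-season* — 1 July to 30 June, labelled by its
starting year — as the unit of analysis. Raw GPS fixes are deduplicated
(first record per bird and timestamp wins, in file order), averaged to one
mean daily position per UTC calendar date, and indexed on a consecutive
day-of-year axis so the whole winter is monotone in day.

**Date estimation.** Each of the four migration dates is the breakpoint of
a two-segment linear regression of latitude on day. For a candidate break
day *b* in the date's calendar search window, the left segment is fit to
days < *b* and the right to days ≥ *b* (two independent OLS lines, four
parameters, a discontinuity allowed), and the objective is the residual
standard error `sqrt((RSS_left + RSS_right)/(n - 4))`. The search is an
exhaustive integer-day grid over the window; ties (to numerical roundoff)
resolve to the earliest day. A nested-model F-test against the single-line
fit on the same data slice, `F = ((RSS0 - RSS1)/2)/(RSS1/(n - 4))`,
records whether the two-segment structure is supported. The windows are
5 Sep–5 Oct (fall start), 5 Oct–5 Nov (fall end), 10 Apr–10 May (spring
start) and 10 May–10 Jun (spring end). The mid-winter turning day is not a
regression breakpoint: it is the day of minimum mean daily latitude
between fall end and spring start (earliest day on ties). Ordering
(fall start < fall end < turn < spring start < spring end) is enforced;
bird-seasons violating it, or lacking coverage, are excluded from
summaries with a log entry.

**Fitted data slice.** Each date's regression uses the window plus a
30-day margin of extra data on one side only: *before* the window for
start-type dates, *after* it for end-type dates. The two fall windows
adjoin at a single calendar day, so a two-sided margin necessarily drags
the opposite migration leg into the slice; numerically this biases the
fitted break by 3–7 days even on noise-free tracks, because the
contaminated segment's residuals trade off against the break position.
The one-sided slice keeps a single structural break in view; on noise-free
piecewise-linear latitude series recovery is then exact, and on spherical
noise-free tracks exact to ±1 day (see *Numerical conventions*).

**Phase metrics.** A phase's endpoints are the mean daily positions on its
two boundary days. Distance is the great-circle (haversine) separation of
the endpoints on a sphere of radius 6378.137 km; duration is the
boundary-day difference; speed is their ratio; direction is the initial
great-circle bearing from start to end. This start-to-end definition
understates cumulative path length for tortuous tracks — deliberate, as
it matches the phase-displacement estimand. Directions are summarised
with circular statistics (vector-mean direction; circular sd
`sqrt(-2 ln R̄)`), with the arithmetic mean ± sd also reported for
comparability with tables that print linear summaries; within a tight
directional cluster the two agree.

**Range dynamics.** For each month October–April, the positions of all
birds are pooled and a 95 % MCP built: rank positions by great-circle
distance to the pooled centroid, keep the `ceil(0.95 n)` nearest (ties
keep the earlier record), hull the keepers in the lon/lat plane.
Population-level (not per-bird) MCPs are used throughout. Mean snow inside
a footprint is the unweighted mean of raster cells whose centers fall
inside or on the hull (cell-center rule, boundary included — the common
zonal-statistics convention). Three exposure series are compared:
*realized* (month-m raster in the month-m MCP), *stay-north* (month-m
raster in the single 95 % MCP of pooled October + April positions), and
*direct-southwest* (same with pooled January + February positions). The
anchor-month pairs are pooled into one footprint per scenario rather than
averaged over two separate MCPs; a single fixed footprint is the cleaner
reading of a "stay here all winter" counterfactual. Month-to-month
displacement is the great-circle distance between consecutive pooled
centroids — a stable, definition-free summary of range shift — and is
regressed (OLS, t-based p-values) on snow cover at the first month's
footprint and the between-month snow difference.

**Habitat.** Daily positions are annotated by containing-cell lookup in a
categorical land-cover raster (no interpolation; class data). Raw legends
merge to five analysis classes — all forest types and savanna → forest;
grassland; cropland; shrubland; urban — with water and unclassified cells
excluded from every denominator. Composition is the percentage of a
bird's positions per class, for the pooled quick phases (fall + spring
legs, boundary days inclusive) and pooled slow phases (the open interval
between them), and quick-vs-slow differences are tested per class with a
paired t on per-bird share differences. Classes annotated for fewer than
`min_birds_per_class` (default 5) birds in either group are flagged, not
tested.

**Statistics.** Per-bird estimation followed by across-bird summaries and
paired/two-sample t procedures replaces a random-effects formulation:
each bird is its own block, so the paired contrast targets the same
estimand as a bird-level random intercept without a REML engine. The
nested F-test (per segmentation fit) and a chi-square likelihood-ratio
test are provided for model comparison; both are verified to be
null-calibrated (p-values uniform under the null) in the test suite. All
tests are two-sided; p-values are reported raw with no multiplicity
correction.

## The synthetic generator

The generator emulates the study system so the pipeline is testable
end-to-end: it is a *structural* emulation of a four-phase annual cycle,
not a behavioural model.

Movement: each bird draws a breeding origin (default 68.9° N ± 0.7,
57.8° E ± 7.0 — the spread of Arctic study colonies) and five boundary
days, then sits at the origin, flies phase Qf, drifts S1 and S2, flies
Qs, and sits at the arrival point. Each phase follows **one great circle**
anchored at the phase's start: the position on day *t* is the point at
cumulative distance `speed × (t − phase_start)` along the circle. This
makes the noiseless start-to-end bearing and distance equal the
configured direction and `speed × duration` exactly, which is what the
downstream metrics measure. (Re-applying a constant compass bearing every
day would instead trace a rhumb-like curve whose start-to-end great-circle
bearing is ~4° off the configured value at these spans.) Observation
noise is Gaussian in degrees, added independently to recorded latitude
and longitude — adequate at mid-latitudes, mildly anisotropic in metres.

Defaults are the published population statistics: 43 birds (35 F / 8 M);
speeds 107/8/17/100 km/day and bearings 198/251/57/7° for Qf/S1/S2/Qs;
boundary-day means 271/285/401/482/500 on the consecutive axis (28 Sep,
12 Oct, 5 Feb, 27 Apr, 15 May). Where the published duration and date
anchors disagree (they are mutually inconsistent at the few-day level),
the dates win, since dates are what segmentation recovers. Boundary-day
spread is per boundary, default (5, 5, 25, 5, 5) days: the four migration
dates are sharply timed (the published sds of ~7–11 days include
estimation error and between-year variance), while the mid-winter turn is
individually staggered — its published spread is ±40 days — which is also
what smears the population's V-shaped latitude bottom across January and
February. Observation noise defaults to 0.05° (~5 km), the scale of
day-to-day jitter in a daily *mean* of many fixes. Boundaries are drawn
independently per bird with a 3-day minimum gap enforced sequentially.
One percent of records are duplicated at the same timestamp (with fresh
noise) to exercise deduplication. All randomness flows from a single
seed; per-bird substreams are spawned deterministically, so output is
bit-identical across runs.

Snow: monthly rasters on a 0.5° grid (42–85° N, 10–95° E) with value
`100·sigmoid((lat − snowline(month))/width)` plus clipped Gaussian cell
noise (sd 2). The default snowline path 67→61→55→50→48→53→60° N
(Oct→Apr) advances toward the southwest of the winter range through
mid-winter and retreats thereafter, with a 3° transition width. A zero
width gives the step-field limit (100 north of the line, 0 south, 50 on
it).

Land cover: cells draw a class i.i.d. from their latitude band's mixture —
wooded-fields mosaic below 60° N (grassland 0.55, cropland 0.33, forest
0.07, urban 0.05), taiga 60–67° N (forest 0.92), tundra above 67° N
(shrubland 0.55, grassland 0.45). Band edges are placed so the zonation
is consistent with the default kinematics: the slow drift occupies
~53–60° N and stays in the mosaic, while both quick legs cross the taiga
belt.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: stopovers, wind drift, tortuosity within phases
(real daily displacement fluctuates; here it is constant within a phase),
spatially coherent snow anomalies or any longitudinal snow gradient, tag
failure, and between-year variation (one season per run; pool runs with
different seeds for multi-season analyses). Because phase speeds and
bearings are fixed while boundary days vary, birds with extreme turn
dates overshoot to the north-east in late winter; a small tail of
positions can leave the raster extent and is dropped from habitat
annotation with a logged count.

## Numerical conventions

* **Day of year** is non-leap (365-day) in every year; 29 February maps
  to 60, sharing 1 March's index. This keeps date↔index anchors stable
  across years. Consecutive indexing adds 365 for dates after
  31 December of the season's start year.
* **Longitude averaging** is arithmetic, not circular: within-day fix
  clusters span ≪ 1°, where the two agree to ~1e-6° (the discrepancy is
  the third-central-moment term of the small-angle expansion) — far below
  GPS precision. This breaks at the antimeridian, far outside any
  plausible study region for this system.
* **Noiseless recovery is exact to ±1 day on spherical tracks.** Latitude
  along a great circle is mildly curved in time, so the two near-zero-RSS
  vertex assignments at a phase boundary can differ by one day; on truly
  piecewise-linear latitude series recovery is exact.
* **Ties** resolve deterministically everywhere: earliest break day,
  earliest minimum-latitude day, earlier record among equidistant MCP
  points, smaller row then column index for positions on shared raster
  cell edges.
* **Feasibility**: a piecewise candidate needs ≥ 2 points strictly on
  each side with non-constant day values; a simple fit needs ≥ 3 points;
  an MCP needs ≥ 5 positions (collinear hulls are flagged degenerate);
  snow extraction errors if no cell center falls inside the polygon
  (resample on a finer grid).
* Spherical Earth with R = 6378.137 km throughout; ellipsoidal geodesics
  differ by < 0.5 % at these scales.

## Known limitations

* The spring-end search window opens on 10 May while the population mean
  arrival is 15 May with a ±5-day spread, so a meaningful fraction of
  birds ends spring migration before the window opens; their date is
  pinned to the window edge. Recovery within ±2 days therefore runs
  ~80–90 % for that date alone and ≥ 90 % pooled over the four dates.
  Both the window and the arrival mean are study inputs; the pipeline
  reports per-date recovery so the effect is visible.
* The realized and direct-southwest exposure series nearly coincide in
  January–February *by construction* — the direct-southwest footprint is
  defined from the January + February positions — so their ordering in
  those months is a sub-percent residual with seed-dependent sign. The
  robust mid-winter signal is stay-north exceeding both by ~8–20
  percentage points; the robust direct-southwest advantage appears in
  autumn and spring.
* Per-bird variance of slow-phase composition and metrics is inflated
  relative to a field study because the turn-date spread interacts with
  fixed phase speeds (see generator notes); population means remain
  centred on the configured values.
* Problem sizes: all shipped analyses run the default 43-bird single
  season (≈ 14 000 daily positions, 0.5° rasters), which the package
  processes in a few seconds; statistical-calibration checks use 500–1000
  vectorised replicates.
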