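# foxtrot

Analysis pipeline for **foxtrot migration** — the annual movement pattern of
mid-latitude-wintering Arctic raptors (studied in the Rough-legged buzzard,
*Buteo lagopus*) in which quick, directed migration legs alternate with a
slow, continuous directional drift across the over-wintering range. After a
~1500 km fall migration, the birds keep moving all winter: ~1000 km
south-west ahead of the advancing snowline, then back north-east as it
retreats, making the over-wintering range *dynamic* rather than fixed.

The package is for movement ecologists working with GPS tracking tables
(Movebank-dialect CSV) and monthly environmental rasters. It provides:

* **Pre-processing** — deduplicate fixes, average to mean daily positions,
  and index each bird-season (1 July – 30 June) on a *consecutive*
  day-of-year axis (days after 31 December continue 366, 367, …; non-leap
  convention throughout).
* **Segmentation** — estimate the four migration dates per bird by
  piecewise-regression breakpoint search: for each candidate day *b* in a
  calendar window, fit two independent OLS segments of latitude on day
  (day < *b* left, day ≥ *b* right) and pick the *b* minimising the
  residual standard error `sqrt(RSS/(n-4))`, validated against the
  single-line fit by a nested-model F-test. The mid-winter turning day is
  the day of minimum mean daily latitude. The five dates split the year
  into quick fall (Qf), slow south-west drift (S1), slow north-east return
  (S2), and quick spring (Qs).
* **Phase metrics** — great-circle distance, duration, speed, and initial
  bearing of each phase per bird (spherical Earth, R = 6378.137 km), with
  circular direction statistics and quick-vs-slow population contrasts.
* **Range dynamics** — monthly 95 % minimum convex polygons (MCPs) of the
  pooled population, mean fractional snow cover inside each footprint, and
  two counterfactual exposure series: *stay-north* (winter in the
  October + April footprint) and *direct-southwest* (winter in the
  January + February footprint); plus an OLS of month-to-month centroid
  displacement on snow cover and snow change.
* **Habitat annotation** — land-cover class per daily position (five merged
  classes: forest incl. savanna, grassland, cropland, shrubland, urban) and
  quick-vs-slow composition with paired per-bird contrasts.
* **Synthetic data** — a seeded generator producing multi-bird annual
  tracks (four-phase great-circle kinematics with the published movement
  parameters as defaults), monthly snow rasters with an advancing and
  retreating snowline, and a zoned land-cover raster, so the entire
  pipeline is testable without downloads.

Rasters are read and written as plain-text ESRI ASCII grids (`.asc`);
tracks as Movebank-dialect CSV.

## Worked example

```python
from foxtrot.simulate import SimConfig, simulate_dataset
from foxtrot.preprocess import assign_season, daily_means, dedupe_timestamps
from foxtrot.segmentation import estimate_population_bounds, summarize_bounds
from foxtrot.metrics import population_metrics, summarize_phases
from foxtrot.ranges import scenario_series

result, snow, landcover = simulate_dataset(SimConfig(seed=1))
daily = assign_season(daily_means(dedupe_timestamps(result.tracks)))
bounds, _ = estimate_population_bounds(daily)

dates = summarize_bounds(bounds, daily).set_index("boundary")
print("fall migration: day %.0f -> %.0f (lat %.2f at end)" % (
    dates.loc["fall_start", "doy_mean"], dates.loc["fall_end", "doy_mean"],
    dates.loc["fall_end", "lat_mean"]))

table = summarize_phases(population_metrics(daily, bounds)).set_index("phase")
for ph in ("Qf", "S1", "S2", "Qs"):
    r = table.loc[ph]
    print("%s: %4.0f +/- %3.0f km, %5.1f +/- %4.1f days, %5.1f km/day, %5.1f deg" % (
        ph, r["distance_mean"], r["distance_sd"], r["duration_mean"],
        r["duration_sd"], r["speed_mean"], r["direction_circ_mean"]))

feb = scenario_series(daily, snow).set_index("month").loc[2]
print("February snow: realized %.1f%%, stay-north %.1f%%, direct-southwest %.1f%%"
      % (feb["realized"], feb["stay_north"], feb["direct_southwest"]))
```

Output:

```
fall migration: day 270 -> 288 (lat 55.46 at end)
Qf: 1502 +/- 569 km,  18.1 +/-  8.2 days,  90.7 km/day, 199.1 deg
S1:  897 +/- 211 km, 112.0 +/- 26.3 days,   8.0 km/day, 250.4 deg
S2: 1397 +/- 453 km,  82.3 +/- 26.7 days,  17.0 km/day,  55.8 deg
Qs: 1737 +/- 727 km,  19.4 +/-  6.7 days,  89.1 km/day,   7.1 deg
February snow: realized 76.4%, stay-north 87.7%, direct-southwest 74.5%
```

Reading this: the pipeline recovered a fall migration starting around
consecutive day 270 (late September) and ending near day 288, leaving the
population at ~55.5° N — the north-east edge of the winter range. The quick
phases run an order of magnitude faster than the slow drift (≈90 vs 8–17
km/day) and the drift heads WSW (250°) then ENE (56°). In February a
population that had stayed where fall migration ended would sit in ~88 %
snow cover instead of the ~76 % the drifting population experiences.

## Command line

Each pipeline stage is also a subcommand operating on the plain-text
artifacts:

```
foxtrot simulate --out data/ --seed 1
foxtrot preprocess data/tracks.csv --out daily.csv
foxtrot segment daily.csv --out bounds.csv
foxtrot metrics daily.csv bounds.csv --out metrics.csv --summary summary.csv
foxtrot range daily.csv --snow-dir data/ --out-dir range/
foxtrot habitat daily.csv bounds.csv --landcover data/landcover.asc --out-dir habitat/
```

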