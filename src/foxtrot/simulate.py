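"""Synthetic tracking data and environmental rasters.

Generates the three inputs the analysis pipeline consumes, with the
statistical structure the method assumes, so every downstream stage is
testable without satellite downloads or telemetry archives:

* multi-bird annual GPS tracks following the four-phase annual cycle of a
  mid-latitude-wintering Arctic raptor — stationary breeding residence, a
  quick directed fall migration (Qf), a slow south-westward over-wintering
  drift (S1), a slow north-eastward return drift (S2), and a quick spring
  migration (Qs);
* monthly fractional snow-cover rasters with a snowline advancing
  south-west from October to mid-winter and retreating north-east toward
  April;
* a latitudinally zoned land-cover raster (tundra shrub/grass, taiga
  forest, and a "wooded fields" grassland/cropland mosaic).

Default parameters reproduce the published movement statistics of
GPS-tracked Rough-legged buzzards (43 birds; phase speeds 107/8/17/100
km/day; phase bearings 198/251/57/7 degrees; phase boundaries on
consecutive days-of-year 271/285/401/482/500).

Daily kinematics are exact great-circle steps: each day's new position is
the destination point at the phase's bearing and speed. Observation noise
is added independently to recorded latitude and longitude in degrees —
simple and adequate at mid-latitudes. All randomness flows from one seed;
per-bird substreams are derived deterministically, so output is
bit-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .geo import destination_point
from .raster import Raster

__all__ = [
    "PHASES",
    "BOUNDARY_NAMES",
    "WINTER_MONTHS",
    "SnowModel",
    "LandBand",
    "GridSpec",
    "SimConfig",
    "SimResult",
    "simulate_tracks",
    "simulate_snow",
    "simulate_landcover",
    "simulate_dataset",
]

#: Movement phases of the annual cycle, in order.
PHASES = ("Qf", "S1", "S2", "Qs")

#: The five dates splitting a season, in order.
BOUNDARY_NAMES = ("fall_start", "fall_end", "winter_turn", "spring_start", "spring_end")

#: Over-wintering months, October through April.
WINTER_MONTHS = (10, 11, 12, 1, 2, 3, 4)

#: Land-cover class codes used in rasters (grassland/cropland mosaic etc.).
LANDCOVER_CODES = {1: "forest", 2: "grassland", 3: "cropland", 4: "shrubland", 5: "urban"}
LANDCOVER_NAMES = {v: k for k, v in LANDCOVER_CODES.items()}


@dataclass(frozen=True)
class SnowModel:
    """Monthly snowline path and the shape of the snow-fraction field.

    ``snowline_lat`` maps calendar month (Oct-Apr) to the latitude at which
    fractional snow cover crosses 50 %. The field is a logistic ramp in
    latitude: 100 * sigmoid((lat - snowline) / width), plus clipped
    Gaussian cell noise. The default path descends from 67 deg N in
    October to 48 deg N in February and retreats to 60 deg N by April,
    emulating the south-west advance and north-east retreat of the
    mid-latitude snowline.
    """

    snowline_lat: dict = field(
        default_factory=lambda: {10: 67.0, 11: 61.0, 12: 55.0, 1: 50.0, 2: 48.0, 3: 53.0, 4: 60.0}
    )
    width_deg: float = 3.0
    noise_sd: float = 2.0

    def validate(self) -> None:
        missing = [m for m in WINTER_MONTHS if m not in self.snowline_lat]
        if missing:
            raise ValueError(f"snowline_lat missing months: {missing}")
        if self.width_deg < 0:
            raise ValueError("snow transition width must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("snow noise sd must be >= 0")


@dataclass(frozen=True)
class LandBand:
    """One latitude band of the zoned land-cover field.

    ``weights`` are per-class sampling probabilities; cells in the band
    draw a class i.i.d. from them. Bands are [lat_lo, lat_hi).
    """

    lat_lo: float
    lat_hi: float
    weights: dict

    def validate(self) -> None:
        if not self.lat_lo < self.lat_hi:
            raise ValueError("band lat_lo must be < lat_hi")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("class weights must be >= 0")
        tot = sum(self.weights.values())
        if not np.isclose(tot, 1.0):
            raise ValueError(f"class weights must sum to 1, got {tot}")
        unknown = set(self.weights) - set(LANDCOVER_NAMES)
        if unknown:
            raise ValueError(f"unknown land-cover classes: {sorted(unknown)}")


@dataclass(frozen=True)
class GridSpec:
    """Raster extent and square cell size (degrees)."""

    lat_min: float = 42.0
    lat_max: float = 85.0
    lon_min: float = 10.0
    lon_max: float = 95.0
    cellsize: float = 0.5

    def empty(self) -> Raster:
        return Raster.from_bounds(self.lat_min, self.lat_max, self.lon_min, self.lon_max, self.cellsize)


def _default_bands() -> tuple[LandBand, ...]:
    # Band edges are placed so the zonation is consistent with the default
    # kinematics: the slow winter drift (latitudes ~53-60 under the default
    # speeds/bearings/dates) stays in the wooded-fields mosaic while both
    # quick migration legs cross the taiga belt below the tundra breeding
    # grounds.
    return (
        # wooded fields: open grassland/cropland mosaic with scattered forest
        LandBand(42.0, 60.0, {"grassland": 0.55, "cropland": 0.33, "forest": 0.07, "urban": 0.05}),
        # taiga: closed forest
        LandBand(60.0, 67.0, {"forest": 0.92, "shrubland": 0.05, "grassland": 0.03}),
        # tundra: shrub and grass, no trees
        LandBand(67.0, 85.0, {"shrubland": 0.55, "grassland": 0.45}),
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    The movement defaults are the published population statistics of the
    tracked Rough-legged buzzards: 43 birds (35 female, 8 male), phase
    speeds in km/day and bearings in degrees clockwise from north per
    phase, and mean boundary days on the consecutive day-of-year axis
    (days after 31 December continue 366, 367, ...). ``phase_start_sd``
    is the between-individual spread of each boundary day (one value per
    boundary, or a single scalar for all five); the default keeps the
    four migration dates tight and the mid-winter turn broad, matching
    the published pattern of a sharply timed migration with individually
    staggered turning days.
    """

    n_birds: int = 43
    frac_female: float = 35.0 / 43.0
    phase_speeds: dict = field(
        default_factory=lambda: {"Qf": 107.0, "S1": 8.0, "S2": 17.0, "Qs": 100.0}
    )
    phase_directions: dict = field(
        default_factory=lambda: {"Qf": 198.0, "S1": 251.0, "S2": 57.0, "Qs": 7.0}
    )
    phase_start_doys: tuple = (271.0, 285.0, 401.0, 482.0, 500.0)
    phase_start_sd: tuple = (5.0, 5.0, 25.0, 5.0, 5.0)
    position_noise_sd: float = 0.05
    breeding_origin: tuple = (68.9, 57.8)
    breeding_spread: tuple = (0.7, 7.0)
    track_start_doy: int = 210
    track_end_doy: int = 545
    start_year: int = 2014
    duplicate_rate: float = 0.01
    snow: SnowModel = field(default_factory=SnowModel)
    landcover_bands: tuple = field(default_factory=_default_bands)
    grid: GridSpec = field(default_factory=GridSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_birds < 1:
            raise ValueError("n_birds must be >= 1")
        if not 0.0 <= self.frac_female <= 1.0:
            raise ValueError("frac_female must be in [0, 1]")
        if set(self.phase_speeds) != set(PHASES) or set(self.phase_directions) != set(PHASES):
            raise ValueError(f"phase_speeds and phase_directions must cover phases {PHASES}")
        if any(v <= 0 for v in self.phase_speeds.values()):
            raise ValueError("phase speeds must be > 0")
        if any(not 0.0 <= d < 360.0 for d in self.phase_directions.values()):
            raise ValueError("phase directions must lie in [0, 360)")
        if len(self.phase_start_doys) != 5 or any(np.diff(self.phase_start_doys) <= 0):
            raise ValueError("phase_start_doys must be five increasing boundary days")
        sds = np.atleast_1d(np.asarray(self.phase_start_sd, dtype=float))
        if sds.size not in (1, 5) or (sds < 0).any():
            raise ValueError("phase_start_sd must be one or five non-negative values")
        if self.position_noise_sd < 0:
            raise ValueError("position_noise_sd must be >= 0")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must be in [0, 1)")
        if not (self.track_start_doy < self.phase_start_doys[0]
                and self.phase_start_doys[-1] < self.track_end_doy):
            raise ValueError("track day span must contain all phase boundaries")
        self.snow.validate()
        bands = sorted(self.landcover_bands, key=lambda b: b.lat_lo)
        for b in bands:
            b.validate()
        for a, b in zip(bands, bands[1:]):
            if b.lat_lo < a.lat_hi:
                raise ValueError(f"land-cover bands overlap at latitude {b.lat_lo}")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimResult:
    """Output of :func:`simulate_tracks`.

    ``tracks`` holds the raw position records (``bird_id``, ``timestamp``,
    ``lat``, ``lon``) in file order, duplicates included. ``birds`` holds
    one row per bird with its sex and the generator's true phase-boundary
    days — the ground truth that segmentation should recover.
    """

    tracks: pd.DataFrame
    birds: pd.DataFrame
    config: SimConfig


def _doy_to_timestamp(doy: int, start_year: int) -> datetime:
    """Consecutive day-of-year -> noon UTC timestamp in the season starting ``start_year``."""
    return datetime(start_year, 1, 1, 12, 0, 0, tzinfo=timezone.utc) + timedelta(days=int(doy) - 1)


def _draw_boundaries(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Per-bird boundary days: Gaussian around the configured means, rounded,
    with a minimum 3-day gap enforced sequentially to keep phases ordered."""
    b = np.rint(rng.normal(cfg.phase_start_doys, cfg.phase_start_sd)).astype(int)
    for i in range(1, 5):
        b[i] = max(b[i], b[i - 1] + 3)
    return b


def simulate_tracks(config: SimConfig | None = None) -> SimResult:
    """Generate raw position records for all birds.

    Each bird resides at a Gaussian-drawn breeding origin, then takes one
    exact great-circle step per day at the active phase's speed and
    bearing; boundary days are drawn per bird around the configured means.
    Recorded positions carry independent Gaussian lat/lon noise, and a
    configured fraction of records is duplicated at the same timestamp
    (with freshly drawn noise) to exercise pre-processing.

    Deterministic for a fixed seed.
    """
    cfg = config or SimConfig()
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_birds)
    n_days = cfg.track_end_doy - cfg.track_start_doy + 1
    doys = np.arange(cfg.track_start_doy, cfg.track_end_doy + 1)

    rows = []
    bird_meta = []
    n_female = int(round(cfg.frac_female * cfg.n_birds))
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        bird_id = f"RLB{i + 1:03d}"
        sex = "F" if i < n_female else "M"
        origin = (
            rng.normal(cfg.breeding_origin[0], cfg.breeding_spread[0]),
            rng.normal(cfg.breeding_origin[1], cfg.breeding_spread[1]),
        )
        bounds = _draw_boundaries(rng, cfg)

        # Each phase travels along one great circle anchored at the phase's
        # start position: position(t) = destination at cumulative distance
        # speed * (t - phase_start) along the circle. Start-to-end initial
        # bearing and great-circle distance then equal the configured
        # direction and speed * duration exactly.
        lat = np.full(n_days, origin[0])
        lon = np.full(n_days, origin[1])
        anchor = origin
        for phase, b0, b1 in zip(PHASES, bounds[:-1], bounds[1:]):
            active = (doys >= b0) & (doys <= b1)
            plat, plon = destination_point(
                anchor[0],
                anchor[1],
                cfg.phase_directions[phase],
                cfg.phase_speeds[phase] * (doys[active] - b0).astype(float),
            )
            lat[active], lon[active] = plat, plon
            anchor = destination_point(
                anchor[0], anchor[1], cfg.phase_directions[phase],
                cfg.phase_speeds[phase] * float(b1 - b0),
            )
        after = doys > bounds[-1]
        lat[after], lon[after] = anchor[0], anchor[1]

        obs_lat = lat + rng.normal(0.0, cfg.position_noise_sd, n_days)
        obs_lon = lon + rng.normal(0.0, cfg.position_noise_sd, n_days)
        dup = rng.random(n_days) < cfg.duplicate_rate
        dup_noise = rng.normal(0.0, cfg.position_noise_sd, (n_days, 2))

        for k in range(n_days):
            ts = _doy_to_timestamp(doys[k], cfg.start_year)
            rows.append((bird_id, ts, obs_lat[k], obs_lon[k]))
            if dup[k]:
                rows.append((bird_id, ts, lat[k] + dup_noise[k, 0], lon[k] + dup_noise[k, 1]))

        bird_meta.append((bird_id, sex, *bounds, origin[0], origin[1]))

    tracks = pd.DataFrame(rows, columns=["bird_id", "timestamp", "lat", "lon"])
    birds = pd.DataFrame(
        bird_meta,
        columns=["bird_id", "sex", *BOUNDARY_NAMES, "origin_lat", "origin_lon"],
    )
    return SimResult(tracks=tracks, birds=birds, config=cfg)


def simulate_snow(config: SimConfig | None = None) -> dict[int, Raster]:
    """Monthly fractional snow-cover rasters for October through April.

    Cell value = 100 * sigmoid((cell_lat - snowline_lat(month)) / width)
    plus clipped Gaussian noise, so snow fraction is ~100 % well north of
    the snowline and ~0 % well south of it, crossing 50 % on the line. A
    zero transition width yields the step-field limit. Values lie in
    [0, 100]; grids are identical across months.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    base = cfg.grid.empty()
    out: dict[int, Raster] = {}
    lat_col = base.lats[:, None]
    for month in WINTER_MONTHS:
        line = cfg.snow.snowline_lat[month]
        if cfg.snow.width_deg == 0.0:
            vals = np.where(lat_col > line, 100.0, np.where(lat_col == line, 50.0, 0.0))
            vals = np.broadcast_to(vals, (base.lats.size, base.lons.size)).copy()
        else:
            vals = 100.0 / (1.0 + np.exp(-(lat_col - line) / cfg.snow.width_deg))
            vals = np.broadcast_to(vals, (base.lats.size, base.lons.size)).copy()
        if cfg.snow.noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.snow.noise_sd, vals.shape)
        out[month] = Raster(base.lats, base.lons, np.clip(vals, 0.0, 100.0))
    return out


def simulate_landcover(config: SimConfig | None = None) -> Raster:
    """Zoned categorical land-cover raster.

    Each cell draws a class i.i.d. from its latitude band's mixture
    weights (seeded, so identical across runs). Values are the integer
    codes of :data:`LANDCOVER_CODES`.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    base = cfg.grid.empty()
    values = np.zeros((base.lats.size, base.lons.size), dtype=int)
    bands = sorted(cfg.landcover_bands, key=lambda b: b.lat_lo)
    covered = np.zeros(base.lats.size, dtype=bool)
    for band in bands:
        in_band = (base.lats >= band.lat_lo) & (base.lats < band.lat_hi)
        covered |= in_band
        if not in_band.any():
            continue
        classes = sorted(band.weights)
        codes = np.array([LANDCOVER_NAMES[c] for c in classes])
        probs = np.array([band.weights[c] for c in classes])
        draw = rng.choice(codes, size=(int(in_band.sum()), base.lons.size), p=probs)
        values[in_band] = draw
    if not covered.all():
        missing = base.lats[~covered]
        raise ValueError(
            f"land-cover bands do not cover grid latitudes {missing.min():.2f}..{missing.max():.2f}"
        )
    return Raster(base.lats, base.lons, values)


def simulate_dataset(config: SimConfig | None = None) -> tuple[SimResult, dict[int, Raster], Raster]:
    """Convenience wrapper: tracks, monthly snow rasters, and land cover."""
    cfg = config or SimConfig()
    return simulate_tracks(cfg), simulate_snow(cfg), simulate_landcover(cfg)
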