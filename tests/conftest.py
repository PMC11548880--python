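"""Shared fixtures: one default-condition simulation and its pipeline
products, computed once per session (the full chain runs in ~2 s)."""

import logging

import pytest

from foxtrot.metrics import population_metrics
from foxtrot.preprocess import assign_season, daily_means, dedupe_timestamps
from foxtrot.segmentation import estimate_population_bounds
from foxtrot.simulate import SimConfig, simulate_dataset, simulate_tracks

logging.getLogger("foxtrot").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sim_default():
    """Default study conditions (43 birds, published movement parameters), seed 0."""
    return simulate_dataset(SimConfig())


@pytest.fixture(scope="session")
def daily_default(sim_default):
    tracks = sim_default[0].tracks
    return assign_season(daily_means(dedupe_timestamps(tracks)))


@pytest.fixture(scope="session")
def bounds_default(sim_default, daily_default):
    bounds, failures = estimate_population_bounds(daily_default)
    return bounds


@pytest.fixture(scope="session")
def metrics_default(daily_default, bounds_default):
    return population_metrics(daily_default, bounds_default)


@pytest.fixture(scope="session")
def sim_noiseless():
    """Three birds with no observation noise, no boundary spread, no duplicates."""
    cfg = SimConfig(
        n_birds=3,
        position_noise_sd=0.0,
        phase_start_sd=(0.0, 0.0, 0.0, 0.0, 0.0),
        duplicate_rate=0.0,
        seed=0,
    )
    return simulate_tracks(cfg)


@pytest.fixture(scope="session")
def daily_noiseless(sim_noiseless):
    return assign_season(daily_means(dedupe_timestamps(sim_noiseless.tracks)))
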