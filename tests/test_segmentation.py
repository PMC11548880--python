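"""Breakpoint search: OLS oracles, exhaustive-search equivalence, recovery."""

import numpy as np
import pandas as pd
import pytest

from foxtrot.segmentation import (
    DEFAULT_WINDOWS,
    SearchWindow,
    estimate_phase_bounds,
    estimate_population_bounds,
    fit_piecewise,
    fit_simple,
    search_break,
    winter_turn,
)
from foxtrot.simulate import BOUNDARY_NAMES


def _track(doys, lats, bird="b1"):
    return pd.DataFrame(
        {"bird_id": bird, "season_year": 2014, "doy": doys, "lat": lats, "lon": 40.0}
    )


# -- simple fit -------------------------------------------------------------


def test_simple_fit_collinear_zero_rss():
    x = np.arange(250, 270, dtype=float)
    fit = fit_simple(x, 3.0 * x - 5.0)
    assert fit.rss == pytest.approx(0.0, abs=1e-18)
    assert fit.slope == pytest.approx(3.0, abs=1e-12)


def test_simple_fit_rejects_two_points_and_degenerate_days():
    with pytest.raises(ValueError):
        fit_simple([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        fit_simple([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


def test_simple_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(3)
    x = rng.uniform(200, 300, 40)
    y = 60.0 - 0.1 * x + rng.normal(0, 0.5, 40)
    fit = fit_simple(x, y)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    assert fit.slope == pytest.approx(beta[0], abs=1e-10)
    assert fit.intercept == pytest.approx(beta[1], abs=1e-10)
    assert fit.rss == pytest.approx(float(resid @ resid), rel=1e-10)


# -- piecewise fit ----------------------------------------------------------


def test_piecewise_exact_on_two_segments():
    x = np.arange(250.0, 300.0)
    y = np.where(x < 271, 68.9, 68.9 - 0.9 * (x - 271))
    fit = fit_piecewise(x, y, 271)
    assert fit is not None
    assert fit.rss == pytest.approx(0.0, abs=1e-16)


def test_piecewise_infeasible_outside_data_range():
    x = np.arange(250.0, 300.0)
    assert fit_piecewise(x, x, 249) is None
    assert fit_piecewise(x, x, 400) is None


def test_piecewise_rss_equals_sum_of_side_fits():
    rng = np.random.default_rng(4)
    x = np.arange(250.0, 320.0)
    y = rng.normal(55, 2, x.size)
    for b in (260, 280, 300):
        fit = fit_piecewise(x, y, b)
        expected = 0.0
        for side in (x < b, x >= b):
            coef = np.polyfit(x[side], y[side], 1)
            expected += float(((y[side] - np.polyval(coef, x[side])) ** 2).sum())
        assert fit.rss == pytest.approx(expected, rel=1e-9)


# -- breakpoint search ------------------------------------------------------


def _brute_force_break(track, window):
    """Independent exhaustive search using numpy.polyfit per side."""
    sl = track[(track["doy"] >= window.fit_lo) & (track["doy"] <= window.fit_hi)]
    x = sl["doy"].to_numpy(dtype=float)
    y = sl["lat"].to_numpy(dtype=float)
    best_b, best_rse = None, np.inf
    for b in range(window.doy_lo, window.doy_hi + 1):
        left, right = x < b, x >= b
        if left.sum() < 2 or right.sum() < 2:
            continue
        if np.ptp(x[left]) == 0 or np.ptp(x[right]) == 0:
            continue
        rss = 0.0
        for side in (left, right):
            coef = np.polyfit(x[side], y[side], 1)
            rss += float(((y[side] - np.polyval(coef, x[side])) ** 2).sum())
        rse = np.sqrt(rss / (x.size - 4))
        if rse < best_rse - 1e-15:
            best_b, best_rse = b, rse
    return best_b, best_rse


def test_search_equals_exhaustive_oracle_on_noisy_tracks():
    rng = np.random.default_rng(5)
    window = SearchWindow("fall_start", 248, 278, extend="before")
    for rep in range(5):
        x = np.arange(window.fit_lo, window.fit_hi + 1, dtype=float)
        y = np.where(x < 265, 68.0, 68.0 - 0.9 * (x - 265)) + rng.normal(0, 0.3, x.size)
        track = _track(x, y)
        fit = search_break(track, window)
        b_oracle, rse_oracle = _brute_force_break(track, window)
        assert fit.break_doy == b_oracle
        assert fit.rse_piecewise == pytest.approx(rse_oracle, rel=1e-9)


def test_search_exact_on_piecewise_linear_latitude():
    """With truly piecewise-linear latitude the minimiser is the vertex day
    exactly (ties resolve to the earlier of the two zero-RSS candidates)."""
    for true_break in (255, 264, 271, 277):
        window = SearchWindow("fall_start", 248, 278, extend="before")
        x = np.arange(window.fit_lo, window.fit_hi + 1, dtype=float)
        y = np.where(x <= true_break, 68.9, 68.9 - 0.9 * (x - true_break))
        fit = search_break(_track(x, y), window)
        assert fit.break_doy == true_break


def test_search_noiseless_spherical_recovery_and_f_test(daily_noiseless, sim_noiseless):
    """On noise-free spherical tracks recovery is exact up to the one-day
    vertex ambiguity left by the slight curvature of great-circle latitude."""
    truth = sim_noiseless.birds.iloc[0]
    trk = daily_noiseless[daily_noiseless["bird_id"] == truth["bird_id"]]
    for w in DEFAULT_WINDOWS:
        fit = search_break(trk, w)
        assert abs(fit.break_doy - truth[w.label]) <= 1
        assert fit.p_value < 1e-6  # two-segment model overwhelmingly better
        assert fit.rse_piecewise <= fit.rse_simple


def test_search_tie_goes_to_smallest_day():
    # flat series: every candidate fits equally badly (rse equal) -> earliest wins
    window = SearchWindow("fall_start", 260, 270, fit_margin=10, extend="before")
    x = np.arange(window.fit_lo, window.fit_hi + 1, dtype=float)
    fit = search_break(_track(x, np.full_like(x, 55.0)), window)
    assert fit.break_doy == window.doy_lo


def test_search_requires_window_coverage():
    window = SearchWindow("fall_start", 248, 278, extend="before")
    x = np.arange(218.0, 260.0)  # stops before the window's upper edge
    with pytest.raises(ValueError, match="cover"):
        search_break(_track(x, x), window)


def test_piecewise_never_worse_than_simple_in_rss():
    rng = np.random.default_rng(6)
    window = SearchWindow("fall_start", 248, 278, extend="before")
    x = np.arange(window.fit_lo, window.fit_hi + 1, dtype=float)
    for rep in range(10):
        y = rng.normal(60, 1, x.size)
        fit = search_break(_track(x, y), window)
        n = fit.n_obs
        rss_pw = fit.rse_piecewise**2 * (n - 4)
        rss_sm = fit.rse_simple**2 * (n - 2)
        assert rss_pw <= rss_sm + 1e-9


# -- winter turn ------------------------------------------------------------


def test_winter_turn_v_shape_vertex():
    doys = np.arange(300, 460)
    lats = np.abs(doys - 401) * 0.05 + 50.0
    assert winter_turn(_track(doys, lats), 300, 459) == 401


def test_winter_turn_plateau_tie_earliest():
    doys = np.arange(300, 320)
    lats = np.where((doys >= 309) & (doys <= 311), 50.0, 55.0)
    assert winter_turn(_track(doys, lats), 300, 319) == 309


def test_winter_turn_empty_range_rejected():
    with pytest.raises(ValueError):
        winter_turn(_track(np.arange(300, 310), np.zeros(10)), 400, 480)


# -- composition ------------------------------------------------------------


def test_noiseless_bounds_recover_generator(daily_noiseless, sim_noiseless):
    """Noise-free tracks: winter turn exact; the four regression dates exact
    up to the one-day great-circle-curvature vertex ambiguity."""
    for _, truth in sim_noiseless.birds.iterrows():
        trk = daily_noiseless[daily_noiseless["bird_id"] == truth["bird_id"]]
        pb = estimate_phase_bounds(trk)
        assert pb.complete() and pb.ordered()
        assert pb.winter_turn == truth["winter_turn"]
        for name in ("fall_start", "fall_end", "spring_start", "spring_end"):
            assert abs(getattr(pb, name) - truth[name]) <= 1, name


def test_track_missing_spring_gives_partial_bounds(daily_noiseless):
    trk = daily_noiseless[daily_noiseless["bird_id"] == "RLB001"]
    trimmed = trk[trk["doy"] < 430]  # tag died mid-winter
    pb = estimate_phase_bounds(trimmed)
    assert pb.fall_start is not None and pb.fall_end is not None
    assert pb.spring_start is None and pb.spring_end is None
    assert pb.winter_turn is None  # needs spring_start
    assert not pb.complete()


def test_population_bounds_excludes_failures(daily_noiseless):
    daily = daily_noiseless.copy()
    # cripple one bird: remove everything after fall migration
    keep = ~((daily["bird_id"] == "RLB002") & (daily["doy"] > 320))
    bounds, failures = estimate_population_bounds(daily[keep])
    assert len(bounds) == 2
    assert len(failures) == 1 and failures[0].bird_id == "RLB002"
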