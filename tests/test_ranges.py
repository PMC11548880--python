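"""Monthly MCPs, zonal snow extraction, counterfactual series, regression."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from foxtrot.raster import Raster
from foxtrot.ranges import (
    consecutive_shifts,
    extract_mean_snow,
    mcp_from_positions,
    monthly_mcp,
    scenario_contrast,
    scenario_series,
    shift_vs_snow_regression,
)
from foxtrot.simulate import WINTER_MONTHS


def _positions(lats, lons, month=1):
    n = len(lats)
    return pd.DataFrame(
        {
            "bird_id": [f"b{i % 3}" for i in range(n)],
            "date": [dt.date(2015, month, 1 + i % 28) for i in range(n)],
            "lat": lats,
            "lon": lons,
        }
    )


def test_retention_count_is_ceiling():
    rng = np.random.default_rng(0)
    pts = _positions(rng.normal(50, 1, 20), rng.normal(40, 1, 20))
    r = mcp_from_positions(pts, month=1, level=0.95)
    assert len(r.retained) == 19  # ceil(0.95 * 20)


def test_full_level_hull_of_square_corners():
    lats = [50.0, 50.0, 52.0, 52.0, 51.0]
    lons = [40.0, 42.0, 40.0, 42.0, 41.0]
    r = mcp_from_positions(_positions(lats, lons), month=1, level=1.0)
    assert r.hull.equals(box(40.0, 50.0, 42.0, 52.0))
    assert r.area == pytest.approx(4.0)


def test_hull_area_matches_shoelace_oracle():
    rng = np.random.default_rng(1)
    pts = _positions(rng.normal(50, 1, 60), rng.normal(40, 2, 60))
    r = mcp_from_positions(pts, month=1)
    xs, ys = r.hull.exterior.coords.xy
    xs, ys = np.asarray(xs), np.asarray(ys)
    shoelace = 0.5 * abs(np.sum(xs[:-1] * ys[1:] - xs[1:] * ys[:-1]))
    assert r.area == pytest.approx(shoelace, rel=1e-12)


def test_hull_contains_all_retained_points():
    rng = np.random.default_rng(2)
    pts = _positions(rng.normal(50, 1, 40), rng.normal(40, 1, 40))
    r = mcp_from_positions(pts, month=1)
    from shapely.geometry import Point

    for _, p in r.points.loc[r.retained].iterrows():
        assert r.hull.covers(Point(p["lon"], p["lat"]))


def test_area_monotone_in_level():
    rng = np.random.default_rng(3)
    pts = _positions(rng.normal(50, 1, 80), rng.normal(40, 1, 80))
    areas = [
        mcp_from_positions(pts, month=1, level=lv).area
        for lv in np.linspace(0.5, 1.0, 11)
    ]
    assert np.all(np.diff(areas) >= -1e-12)


def test_too_few_positions_rejected():
    with pytest.raises(ValueError):
        mcp_from_positions(_positions([50, 50, 51, 51], [40, 41, 40, 41]), month=1)


def test_collinear_positions_flagged_degenerate():
    lats = [50.0, 50.5, 51.0, 51.5, 52.0]
    r = mcp_from_positions(_positions(lats, [40.0] * 5), month=1, level=1.0)
    assert r.degenerate


# -- snow extraction --------------------------------------------------------


def _uniform_raster(value, cellsize=0.5):
    r = Raster.from_bounds(45.0, 60.0, 30.0, 50.0, cellsize)
    r.values[:] = value
    return r


def test_extract_uniform_raster():
    poly = box(35.0, 50.0, 40.0, 55.0)
    assert extract_mean_snow(_uniform_raster(37.5), poly) == pytest.approx(37.5)


def test_extract_half_plane_split():
    r = _uniform_raster(0.0, cellsize=0.1)
    r.values[r.lats >= 52.5, :] = 100.0
    poly = box(35.0, 50.0, 40.0, 55.0)  # split evenly at 52.5
    got = extract_mean_snow(r, poly)
    assert got == pytest.approx(50.0, abs=2.0)  # one-cell discretization slack


def test_extract_polygon_south_of_snowline_step():
    r = _uniform_raster(0.0)
    r.values[r.lats >= 55.0, :] = 100.0
    assert extract_mean_snow(r, box(35.0, 46.0, 40.0, 50.0)) == 0.0


def test_extract_no_overlap_rejected():
    with pytest.raises(ValueError):
        extract_mean_snow(_uniform_raster(5.0), box(100.0, 10.0, 105.0, 12.0))


def test_extract_bounded_by_raster_range():
    rng = np.random.default_rng(4)
    r = _uniform_raster(0.0)
    r.values[:] = rng.uniform(0, 100, r.values.shape)
    poly = Polygon([(33, 47), (44, 48), (41, 58), (34, 55)])
    got = extract_mean_snow(r, poly)
    assert r.values.min() <= got <= r.values.max()


# -- scenarios --------------------------------------------------------------


def _winter_daily(move=True, seed=0):
    """Small synthetic winter: 8 birds drifting SW then back NE (or parked)."""
    rng = np.random.default_rng(seed)
    rows = []
    months = [(2014, 10), (2014, 11), (2014, 12), (2015, 1), (2015, 2), (2015, 3), (2015, 4)]
    for b in range(8):
        lat0 = 56.0 + rng.normal(0, 0.5)
        lon0 = 48.0 + rng.normal(0, 1.0)
        for k, (yy, mm) in enumerate(months):
            shift = min(k, 6 - k) if move else 0  # V-shaped drift, vertex mid-winter
            for d in range(1, 29, 3):
                rows.append(
                    {
                        "bird_id": f"b{b}",
                        "season_year": 2014,
                        "date": dt.date(yy, mm, d),
                        "lat": lat0 - 2.0 * shift + rng.normal(0, 0.1),
                        "lon": lon0 - 3.0 * shift + rng.normal(0, 0.2),
                    }
                )
    return pd.DataFrame(rows)


def _snow_set(value_fn):
    return {m: value_fn(m) for m in WINTER_MONTHS}


def test_uniform_snow_makes_all_scenarios_equal():
    daily = _winter_daily()
    snow = _snow_set(lambda m: _uniform_raster(42.0))
    series = scenario_series(daily, snow)
    for col in ("realized", "stay_north", "direct_southwest"):
        np.testing.assert_allclose(series[col], 42.0)


def test_fixed_footprint_scenarios_constant_under_identical_rasters():
    rng = np.random.default_rng(5)
    r = _uniform_raster(0.0)
    r.values[:] = rng.uniform(0, 100, r.values.shape)
    daily = _winter_daily()
    series = scenario_series(daily, _snow_set(lambda m: r))
    # stay_north and direct_southwest use one fixed footprint each
    assert series["stay_north"].nunique() == 1
    assert series["direct_southwest"].nunique() == 1


def test_stationary_population_collapses_scenarios():
    daily = _winter_daily(move=False)
    r = _uniform_raster(0.0)
    r.values[:] = np.linspace(0, 100, r.values.shape[0])[:, None]
    series = scenario_series(daily, _snow_set(lambda m: r))
    spread = series[["realized", "stay_north", "direct_southwest"]].to_numpy()
    assert np.ptp(spread) < 5.0  # within footprint-sampling discretization


def test_scenario_contrast_arithmetic_and_identity():
    series = pd.DataFrame(
        {
            "month": [1, 2],
            "realized": [57.3, 85.1],
            "stay_north": [60.0, 99.5],
            "direct_southwest": [31.6, 85.1],
        }
    )
    out = scenario_contrast(series)
    assert out.loc[1, "stay_minus_realized"] == pytest.approx(14.4, abs=1e-9)
    assert out.loc[0, "realized_minus_southwest"] == pytest.approx(25.7, abs=1e-9)
    same = series.assign(stay_north=series["realized"], direct_southwest=series["realized"])
    z = scenario_contrast(same)
    np.testing.assert_allclose(z["stay_minus_realized"], 0.0)
    np.testing.assert_allclose(z["realized_minus_southwest"], 0.0)


def test_centroid_distances_symmetric_under_month_reversal():
    daily = _winter_daily()
    snow = _snow_set(lambda m: _uniform_raster(10.0))
    fwd = consecutive_shifts(daily, snow)
    rev = consecutive_shifts(daily, snow, months=tuple(reversed(WINTER_MONTHS)))
    np.testing.assert_allclose(
        fwd["centroid_distance_km"].to_numpy(),
        rev["centroid_distance_km"].to_numpy()[::-1],
        rtol=1e-12,
    )


# -- displacement regression ------------------------------------------------


def test_regression_recovers_exact_linear_relation():
    shifts = pd.DataFrame(
        {
            "month_pair": list("abcdef"),
            "snow_at_first": [5.0, 20.0, 40.0, 60.0, 80.0, 95.0],
            "snow_difference": [15.0, 20.0, 20.0, 20.0, 15.0, -10.0],
        }
    )
    shifts["centroid_distance_km"] = 2.0 * shifts["snow_at_first"]
    table = shift_vs_snow_regression(shifts).set_index("term")
    assert table.loc["snow_at_first", "coef"] == pytest.approx(2.0, abs=1e-9)
    assert table.loc["snow_at_first", "p"] < 1e-9
    assert table.loc["intercept", "coef"] == pytest.approx(0.0, abs=1e-8)


def test_regression_matches_normal_equations_oracle():
    rng = np.random.default_rng(6)
    shifts = pd.DataFrame(
        {
            "month_pair": [str(i) for i in range(30)],
            "snow_at_first": rng.uniform(0, 100, 30),
            "snow_difference": rng.normal(10, 5, 30),
        }
    )
    shifts["centroid_distance_km"] = (
        50.0 + 1.5 * shifts["snow_at_first"] - 3.0 * shifts["snow_difference"]
        + rng.normal(0, 20, 30)
    )
    table = shift_vs_snow_regression(shifts)
    X = np.column_stack(
        [np.ones(30), shifts["snow_at_first"], shifts["snow_difference"]]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ shifts["centroid_distance_km"].to_numpy())
    np.testing.assert_allclose(table["coef"].to_numpy(), beta, atol=1e-10)


def test_regression_null_p_values_not_extreme():
    """With displacement independent of both snow covariates, p-values over
    seeded replicates behave like draws from a uniform: roughly the nominal
    fraction falls below 0.1 and small p-values are not systematically produced."""
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(200):
        shifts = pd.DataFrame(
            {
                "month_pair": [str(i) for i in range(12)],
                "snow_at_first": rng.uniform(0, 100, 12),
                "snow_difference": rng.normal(0, 10, 12),
            }
        )
        shifts["centroid_distance_km"] = rng.normal(100, 30, 12)
        t = shift_vs_snow_regression(shifts).set_index("term")
        pvals.append(t.loc["snow_at_first", "p"])
    frac = np.mean(np.asarray(pvals) < 0.1)
    assert 0.04 < frac < 0.18  # 3-sigma band around the nominal 0.1


def test_regression_input_validation():
    shifts = pd.DataFrame(
        {
            "month_pair": list("abc"),
            "snow_at_first": [1.0, 2.0, 3.0],
            "snow_difference": [1.0, 1.0, 1.0],
            "centroid_distance_km": [5.0, 6.0, 7.0],
        }
    )
    with pytest.raises(ValueError, match="month-pairs"):
        shift_vs_snow_regression(shifts)
    collinear = pd.DataFrame(
        {
            "month_pair": list("abcde"),
            "snow_at_first": [1.0, 2.0, 3.0, 4.0, 5.0],
            "snow_difference": [2.0, 4.0, 6.0, 8.0, 10.0],
            "centroid_distance_km": [5.0, 6.0, 7.0, 8.0, 9.0],
        }
    )
    with pytest.raises(ValueError, match="collinear"):
        shift_vs_snow_regression(collinear)


def test_monthly_mcp_needs_month_positions(daily_default):
    r = monthly_mcp(daily_default, 12)
    assert not r.degenerate
    assert len(r.retained) == int(np.ceil(0.95 * len(r.points)))
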