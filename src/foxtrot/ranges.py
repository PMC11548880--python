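"""Dynamic over-wintering range: monthly MCPs and snow-cover scenarios.

The over-wintering distribution is summarised per calendar month
(October-April) by a population-level 95 % minimum convex polygon (MCP):
pool the mean daily positions of all birds in the month, rank them by
great-circle distance to the pooled centroid, retain the ceil(0.95 n)
nearest, and take the convex hull of the retained points in the lon/lat
plane. Month-to-month displacement is the great-circle distance between
consecutive monthly centroids.

Snow exposure under three residency strategies is compared on the monthly
snow rasters:

* ``realized`` — mean snow of month m inside the month-m MCP (what the
  drifting population actually experienced);
* ``stay_north`` — mean snow of month m inside the single 95 % MCP of the
  pooled October + April positions (had the birds stayed where fall
  migration ended, in the north-east of the winter range);
* ``direct_southwest`` — same with the pooled January + February
  positions (had they flown straight to the far south-west and sat out
  the winter there).

Mean snow inside a footprint is the unweighted mean of raster cells whose
centers fall inside (or on the boundary of) the hull polygon. Whether
month-to-month displacement tracks snow is assessed with an OLS of
centroid displacement on snow cover at the first MCP and the
between-month snow difference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from shapely.geometry import MultiPoint

from .geo import haversine_km
from .raster import Raster
from .simulate import WINTER_MONTHS

__all__ = [
    "MonthlyRange",
    "monthly_mcp",
    "mcp_from_positions",
    "extract_mean_snow",
    "scenario_series",
    "scenario_contrast",
    "consecutive_shifts",
    "shift_vs_snow_regression",
]


@dataclass
class MonthlyRange:
    """A month's 95 % MCP of the pooled population.

    ``points`` are all pooled positions used; ``retained`` indexes the
    95 % subset nearest the centroid; ``hull`` is their convex hull in
    the lon/lat plane (a shapely polygon; degenerate — line or point —
    when the retained points are collinear, flagged by ``degenerate``).
    """

    month: int
    points: pd.DataFrame
    retained: np.ndarray
    hull: shapely.Geometry
    centroid: tuple[float, float]  # (lat, lon) mean of points used
    level: float

    @property
    def degenerate(self) -> bool:
        return self.hull.geom_type != "Polygon"

    @property
    def area(self) -> float:
        """Planar hull area in square degrees (lon/lat plane)."""
        return float(self.hull.area)


def mcp_from_positions(points: pd.DataFrame, month: int, level: float = 0.95) -> MonthlyRange:
    """Minimum convex polygon of a set of positions.

    Centroid = arithmetic mean of all positions; the ceil(level * n)
    positions nearest the centroid (great-circle distance; ties keep the
    earlier record) are retained and hulled.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    n = len(points)
    if n < 5:
        raise ValueError(f"MCP needs >= 5 positions, got {n}")
    pts = points.reset_index(drop=True)
    c_lat = float(pts["lat"].mean())
    c_lon = float(pts["lon"].mean())
    dist = haversine_km(pts["lat"].to_numpy(), pts["lon"].to_numpy(), c_lat, c_lon)
    keep = ceil(level * n)
    order = np.argsort(dist, kind="stable")  # stable: ties keep earlier record
    retained = np.sort(order[:keep])
    hull = MultiPoint(
        list(zip(pts.loc[retained, "lon"], pts.loc[retained, "lat"]))
    ).convex_hull
    return MonthlyRange(
        month=month, points=pts, retained=retained, hull=hull,
        centroid=(c_lat, c_lon), level=level,
    )


def monthly_mcp(daily: pd.DataFrame, month: int, level: float = 0.95) -> MonthlyRange:
    """Population MCP for one calendar month, pooling all birds' daily positions."""
    months = pd.to_datetime(daily["date"]).dt.month
    sel = daily[months == month]
    if len(sel) < 5:
        raise ValueError(f"fewer than 5 positions in month {month}")
    return mcp_from_positions(sel, month, level)


def extract_mean_snow(raster: Raster, polygon: shapely.Geometry) -> float:
    """Unweighted mean raster value over cells whose centers lie inside
    (or on the boundary of) the polygon.

    Raises
    ------
    ValueError
        If no cell center is covered — the polygon is smaller than a
        cell; resample the raster on a finer grid.
    """
    lon_min, lat_min, lon_max, lat_max = polygon.bounds
    rows = np.where((raster.lats >= lat_min - raster.cellsize) & (raster.lats <= lat_max + raster.cellsize))[0]
    cols = np.where((raster.lons >= lon_min - raster.cellsize) & (raster.lons <= lon_max + raster.cellsize))[0]
    if rows.size == 0 or cols.size == 0:
        raise ValueError("polygon does not overlap the raster; no covered cells")
    lon_grid, lat_grid = np.meshgrid(raster.lons[cols], raster.lats[rows])
    pts = shapely.points(lon_grid.ravel(), lat_grid.ravel())
    inside = shapely.covers(polygon, pts)  # boundary cells included
    if not inside.any():
        raise ValueError(
            "no raster cell centers inside the polygon; use a finer grid"
        )
    vals = raster.values[np.ix_(rows, cols)].astype(float).ravel()[inside]
    return float(vals.mean())


def scenario_series(
    daily: pd.DataFrame,
    snow: dict[int, Raster],
    level: float = 0.95,
    months: tuple[int, ...] = WINTER_MONTHS,
) -> pd.DataFrame:
    """Month-by-month mean snow under realized and counterfactual strategies.

    Returns
    -------
    DataFrame
        Columns ``month, realized, stay_north, direct_southwest`` — mean
        snow percent in each footprint for each month's raster.
    """
    cal_month = pd.to_datetime(daily["date"]).dt.month
    mcps = {m: monthly_mcp(daily, m, level) for m in months}
    north = mcp_from_positions(daily[cal_month.isin([10, 4])], month=-1, level=level)
    southwest = mcp_from_positions(daily[cal_month.isin([1, 2])], month=-2, level=level)
    rows = []
    for m in months:
        rows.append(
            {
                "month": m,
                "realized": extract_mean_snow(snow[m], mcps[m].hull),
                "stay_north": extract_mean_snow(snow[m], north.hull),
                "direct_southwest": extract_mean_snow(snow[m], southwest.hull),
            }
        )
    return pd.DataFrame(rows)


def scenario_contrast(series: pd.DataFrame) -> pd.DataFrame:
    """Per-month scenario differences.

    ``stay_minus_realized`` is the extra snow a stay-put population would
    have faced; ``realized_minus_southwest`` is the snow saved by going
    all the way south-west immediately. The returned frame carries a
    ``peak`` attribute naming the month with the largest
    stay-minus-realized contrast.
    """
    out = series.copy()
    out["stay_minus_realized"] = out["stay_north"] - out["realized"]
    out["realized_minus_southwest"] = out["realized"] - out["direct_southwest"]
    out.attrs["peak_month"] = int(out.loc[out["stay_minus_realized"].idxmax(), "month"])
    return out


def consecutive_shifts(
    daily: pd.DataFrame,
    snow: dict[int, Raster],
    level: float = 0.95,
    months: tuple[int, ...] = WINTER_MONTHS,
) -> pd.DataFrame:
    """Month-pair displacement and snow covariates.

    For each consecutive month pair: great-circle distance between the
    pooled centroids, mean snow at the first month's MCP (from the first
    month's raster), and the snow difference (second minus first, each on
    its own raster and footprint).
    """
    mcps = {m: monthly_mcp(daily, m, level) for m in months}
    realized = {m: extract_mean_snow(snow[m], mcps[m].hull) for m in months}
    rows = []
    for m1, m2 in itertools.pairwise(months):
        c1, c2 = mcps[m1].centroid, mcps[m2].centroid
        rows.append(
            {
                "month_pair": f"{m1}-{m2}",
                "centroid_distance_km": float(haversine_km(c1[0], c1[1], c2[0], c2[1])),
                "snow_at_first": realized[m1],
                "snow_difference": realized[m2] - realized[m1],
            }
        )
    return pd.DataFrame(rows)


def shift_vs_snow_regression(shifts: pd.DataFrame) -> pd.DataFrame:
    """OLS of monthly displacement on snow cover and snow change.

    Model: centroid_distance ~ snow_at_first + snow_difference. Needs at
    least 4 month-pairs (pool several seasons for power).

    Returns
    -------
    DataFrame
        Coefficient table (term, coef, se, t, p) with t-based p-values.

    Raises
    ------
    ValueError
        On fewer than 4 rows or a rank-deficient design.
    """
    if len(shifts) < 4:
        raise ValueError("need >= 4 month-pairs for the displacement regression")
    X = sm.add_constant(shifts[["snow_at_first", "snow_difference"]].to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: snow covariates are collinear")
    fit = sm.OLS(shifts["centroid_distance_km"].to_numpy(), X).fit()
    return pd.DataFrame(
        {
            "term": ["intercept", "snow_at_first", "snow_difference"],
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
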