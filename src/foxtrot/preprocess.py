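"""Reading and pre-processing of raw tracking tables.

Raw GPS fixes arrive as Movebank-dialect delimited text
(``individual-local-identifier``, ``timestamp``, ``location-lat``,
``location-long``). Pre-processing removes duplicated timestamps (first
occurrence in file order wins), averages fixes to one mean daily position
per bird per UTC calendar date, and places each bird-season on a
*consecutive* day-of-year axis: days after 31 December of the season's
start year continue 366, 367, ... so that a full October-April winter is
monotone in day index.

Day-of-year uses the non-leap (365-day) calendar convention throughout, so
printed date anchors map stably across years (28 Sep = 271, 12 Oct = 285,
5 Feb = 36, 27 Apr = 117, 15 May = 135); 29 February is assigned day 60,
sharing the index of 1 March. A biological season runs 1 July - 30 June,
far from any migration window, and is labelled by its starting year.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path

import pandas as pd

__all__ = [
    "MOVEBANK_COLUMNS",
    "read_tracks",
    "write_tracks",
    "dedupe_timestamps",
    "daily_means",
    "date_to_doy",
    "assign_season",
    "preprocess",
]

logger = logging.getLogger(__name__)

#: Movebank column name -> internal column name.
MOVEBANK_COLUMNS = {
    "individual-local-identifier": "bird_id",
    "timestamp": "timestamp",
    "location-lat": "lat",
    "location-long": "lon",
}

# cumulative days before each month, non-leap calendar
_CUM_DAYS = (0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334)


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a Movebank-dialect CSV of GPS fixes.

    Rows with unparseable timestamps or coordinates, or with coordinates
    outside [-90, 90] x [-180, 180], are dropped and the count logged.

    Returns
    -------
    DataFrame
        Columns ``bird_id`` (str), ``timestamp`` (UTC datetime), ``lat``,
        ``lon`` (float), in file order.

    Raises
    ------
    ValueError
        If a required column is missing (the error names it).
    """
    df = pd.read_csv(path, dtype={"individual-local-identifier": str})
    for col in MOVEBANK_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    df = df[list(MOVEBANK_COLUMNS)].rename(columns=MOVEBANK_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    ok = (
        df["timestamp"].notna()
        & df["bird_id"].notna()
        & df["lat"].between(-90.0, 90.0)
        & df["lon"].between(-180.0, 180.0)
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("dropped %d unparseable/out-of-bounds rows from %s", dropped, path)
    return df.loc[ok].reset_index(drop=True)


def write_tracks(df: pd.DataFrame, path: str | Path) -> None:
    """Write fixes as Movebank-dialect CSV (ISO-8601 UTC timestamps)."""
    out = pd.DataFrame(
        {
            "individual-local-identifier": df["bird_id"],
            "timestamp": pd.to_datetime(df["timestamp"], utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "location-lat": df["lat"],
            "location-long": df["lon"],
        }
    )
    out.to_csv(path, index=False)


def dedupe_timestamps(df: pd.DataFrame) -> pd.DataFrame:
    """Remove duplicated timestamps per bird, keeping the first occurrence
    in file order. The same timestamp on different birds is not a duplicate."""
    return df.drop_duplicates(subset=["bird_id", "timestamp"], keep="first").reset_index(drop=True)


def daily_means(df: pd.DataFrame) -> pd.DataFrame:
    """Mean daily position per bird per UTC calendar date.

    Latitude and longitude are averaged arithmetically; within a day a
    bird's fixes span far less than a degree of longitude, where the
    arithmetic and circular means agree to well below GPS precision (the
    approximation degrades only at the antimeridian, far outside the
    study region).

    Returns
    -------
    DataFrame
        Columns ``bird_id``, ``date`` (datetime.date), ``lat``, ``lon``;
        one row per bird per date, sorted by bird then date.
    """
    g = df.copy()
    g["date"] = pd.to_datetime(g["timestamp"], utc=True).dt.date
    out = (
        g.groupby(["bird_id", "date"], as_index=False, sort=True)[["lat", "lon"]]
        .mean()
    )
    return out


def date_to_doy(date: dt.date) -> int:
    """Day of year under the non-leap (365-day) convention.

    29 February maps to 60, the same index as 1 March; all later dates
    keep their non-leap index regardless of the actual year.
    """
    return _CUM_DAYS[date.month - 1] + date.day


def assign_season(daily: pd.DataFrame) -> pd.DataFrame:
    """Label bird-seasons and build the consecutive day axis.

    A season is the year between two consecutive breeding seasons,
    bounded at 1 July and labelled by its starting calendar year. Dates
    after 31 December get 365 + non-leap DOY, so the axis increases
    through the whole winter.

    Returns
    -------
    DataFrame
        ``bird_id, season_year, date, doy, lat, lon`` sorted by bird,
        season, and day; ``doy`` strictly increasing within a bird-season.
    """
    out = daily.copy()
    dates = pd.to_datetime(out["date"])
    out["date"] = dates.dt.date
    season = dates.dt.year.where(dates.dt.month >= 7, dates.dt.year - 1)
    out["season_year"] = season.astype(int)
    doy = dates.dt.date.map(date_to_doy).astype(int)
    out["doy"] = doy + 365 * (dates.dt.year.to_numpy() - out["season_year"].to_numpy())
    out = out.sort_values(["bird_id", "season_year", "doy"]).reset_index(drop=True)
    dup = out.duplicated(subset=["bird_id", "season_year", "doy"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate bird-days after daily averaging; "
            "was daily_means applied?"
        )
    return out[["bird_id", "season_year", "date", "doy", "lat", "lon"]]


def preprocess(path: str | Path) -> pd.DataFrame:
    """Full pre-processing chain: read, dedupe, daily means, season axis."""
    return assign_season(daily_means(dedupe_timestamps(read_tracks(path))))
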