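"""Per-phase movement metrics and population summaries.

For each bird and phase (Qf fall migration, S1/S2 the two halves of the
over-wintering drift, Qs spring migration) the metrics are defined on the
phase's endpoint positions — the mean daily positions on the two boundary
days:

* distance — great-circle km between start and end position;
* duration — days between the boundary days;
* speed — distance / duration, km/day;
* direction — initial great-circle bearing start -> end, degrees
  clockwise from north.

Population summaries report mean +/- sd per phase across birds; for
directions both the circular mean with circular standard deviation
sqrt(-2 ln Rbar) and the arithmetic mean +/- sd are given (published
tables often print the latter; within a tight directional cluster the
two agree). Derived contrasts mirror the quick-vs-slow comparison: pooled
one-part quick (Qf, Qs) vs slow (S1, S2) distance and duration
differences, the speed ratio, and the turn angles between consecutive
phases.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geo import angular_difference, haversine_km, initial_bearing
from .simulate import PHASES
from .stats import TestResult, two_sample_t

__all__ = [
    "PHASE_ENDPOINTS",
    "phase_metrics",
    "population_metrics",
    "circular_mean",
    "summarize_phases",
    "phase_contrasts",
    "sex_distance_comparison",
]

logger = logging.getLogger(__name__)

#: phase -> (start boundary, end boundary)
PHASE_ENDPOINTS = {
    "Qf": ("fall_start", "fall_end"),
    "S1": ("fall_end", "winter_turn"),
    "S2": ("winter_turn", "spring_start"),
    "Qs": ("spring_start", "spring_end"),
}

QUICK = ("Qf", "Qs")
SLOW = ("S1", "S2")


def phase_metrics(daily_track: pd.DataFrame, bounds: pd.Series | dict) -> pd.DataFrame:
    """Metrics of the four phases for one bird-season.

    ``bounds`` supplies the five boundary days. A phase whose boundary-day
    position is missing from the track is skipped with a log entry.

    Returns
    -------
    DataFrame
        One row per computed phase: ``bird_id, phase, distance_km,
        duration_days, speed_kmday, direction_deg`` plus endpoint
        coordinates.
    """
    bird_id = str(daily_track["bird_id"].iloc[0])
    by_doy = daily_track.set_index("doy")
    rows = []
    for phase in PHASES:
        b0, b1 = PHASE_ENDPOINTS[phase]
        d0, d1 = bounds[b0], bounds[b1]
        if d0 is None or d1 is None or pd.isna(d0) or pd.isna(d1):
            logger.info("bird %s: phase %s skipped, boundary missing", bird_id, phase)
            continue
        d0, d1 = int(d0), int(d1)
        if d0 not in by_doy.index or d1 not in by_doy.index:
            logger.info("bird %s: phase %s skipped, no position on boundary day", bird_id, phase)
            continue
        p0 = by_doy.loc[d0]
        p1 = by_doy.loc[d1]
        dist = float(haversine_km(p0["lat"], p0["lon"], p1["lat"], p1["lon"]))
        dur = d1 - d0
        if dur < 1:
            logger.info("bird %s: phase %s skipped, non-positive duration", bird_id, phase)
            continue
        try:
            direction = float(initial_bearing(p0["lat"], p0["lon"], p1["lat"], p1["lon"]))
        except ValueError:
            direction = float("nan")
        rows.append(
            {
                "bird_id": bird_id,
                "phase": phase,
                "distance_km": dist,
                "duration_days": dur,
                "speed_kmday": dist / dur,
                "direction_deg": direction,
                "start_lat": float(p0["lat"]),
                "start_lon": float(p0["lon"]),
                "end_lat": float(p1["lat"]),
                "end_lon": float(p1["lon"]),
            }
        )
    return pd.DataFrame(rows)


def population_metrics(daily: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    """Phase metrics for every bird-season in a bounds table."""
    parts = []
    for _, row in bounds.iterrows():
        trk = daily[
            (daily["bird_id"] == row["bird_id"])
            & (daily["season_year"] == row["season_year"])
        ]
        if trk.empty:
            continue
        m = phase_metrics(trk, row)
        if not m.empty:
            m.insert(1, "season_year", row["season_year"])
            parts.append(m)
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


def circular_mean(directions_deg: Sequence[float]) -> tuple[float, float]:
    """Circular mean and circular standard deviation of directions.

    The mean is the direction of the resultant vector; the circular sd is
    sqrt(-2 ln Rbar) converted to degrees. With a (near-)zero resultant —
    e.g. an antipodal pair — the mean direction is undefined and
    ``(nan, nan)`` is returned.
    """
    d = np.asarray(directions_deg, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("circular_mean needs at least one direction")
    rad = np.radians(d)
    c, s = np.cos(rad).mean(), np.sin(rad).mean()
    rbar = float(np.hypot(c, s))
    if rbar < 1e-12:
        return float("nan"), float("nan")
    mean = float(np.degrees(np.arctan2(s, c)) % 360.0)
    if mean == 360.0:  # tiny negative angle mod 360 rounds up
        mean = 0.0
    sd = float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(rbar)))))
    return mean, sd


def summarize_phases(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-phase population summary across birds (Table-style).

    One row per phase plus pooled ``quick`` (Qf+Qs) and ``slow`` (S1+S2)
    one-part rows: mean +/- sd of distance, duration, and speed; circular
    and arithmetic direction summaries; n metric values.
    """
    if metrics["bird_id"].nunique() < 2:
        raise ValueError("phase summary needs at least 2 birds")
    groups: list[tuple[str, pd.DataFrame]] = [
        (ph, metrics[metrics["phase"] == ph]) for ph in PHASES
    ]
    groups.append(("quick", metrics[metrics["phase"].isin(QUICK)]))
    groups.append(("slow", metrics[metrics["phase"].isin(SLOW)]))
    rows = []
    for name, g in groups:
        if g.empty:
            continue
        row = {"phase": name, "n": int(len(g))}
        for col, key in (
            ("distance_km", "distance"),
            ("duration_days", "duration"),
            ("speed_kmday", "speed"),
        ):
            row[f"{key}_mean"] = float(g[col].mean())
            row[f"{key}_sd"] = float(g[col].std(ddof=1)) if len(g) > 1 else float("nan")
        dirs = g["direction_deg"].dropna()
        if dirs.empty:
            row["direction_circ_mean"] = row["direction_circ_sd"] = float("nan")
            row["direction_mean"] = row["direction_sd"] = float("nan")
        else:
            cm, csd = circular_mean(dirs)
            row["direction_circ_mean"] = cm
            row["direction_circ_sd"] = csd
            row["direction_mean"] = float(dirs.mean())
            row["direction_sd"] = float(dirs.std(ddof=1)) if len(dirs) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def phase_contrasts(metrics: pd.DataFrame) -> dict:
    """Derived quick-vs-slow contrasts.

    Returns a dict with: pooled one-part quick minus slow distance (km),
    slow minus quick duration (days), S1 minus S2 duration, quick/slow
    speed ratio, and circular-mean turn angles between consecutive phases
    (positive = clockwise).
    """
    summary = summarize_phases(metrics).set_index("phase")
    out = {
        "quick_minus_slow_distance_km": summary.loc["quick", "distance_mean"]
        - summary.loc["slow", "distance_mean"],
        "slow_minus_quick_duration_days": summary.loc["slow", "duration_mean"]
        - summary.loc["quick", "duration_mean"],
        "s1_minus_s2_duration_days": summary.loc["S1", "duration_mean"]
        - summary.loc["S2", "duration_mean"],
        "quick_over_slow_speed_ratio": summary.loc["quick", "speed_mean"]
        / summary.loc["slow", "speed_mean"],
    }
    # per-bird turn angles between consecutive phases, then circular stats
    wide = metrics.pivot_table(
        index=["bird_id", "season_year"], columns="phase", values="direction_deg"
    )
    for a, b in (("Qf", "S1"), ("S1", "S2"), ("S2", "Qs")):
        if a in wide.columns and b in wide.columns:
            both = wide[[a, b]].dropna()
            turns = angular_difference(both[a].to_numpy(), both[b].to_numpy())
            out[f"turn_{a}_to_{b}_deg"] = float(np.mean(turns)) if len(turns) else float("nan")
    return out


def sex_distance_comparison(metrics: pd.DataFrame, sex_table: pd.DataFrame) -> dict:
    """Compare quick-phase migration distance between the sexes.

    Per-bird mean quick-phase (Qf, Qs) distance is the unit of analysis;
    groups are compared with a Welch two-sample t-test. If either sex is
    absent (or has < 3 birds) the comparison is skipped with a flag.

    Parameters
    ----------
    metrics : DataFrame
        Output of :func:`population_metrics`.
    sex_table : DataFrame
        Columns ``bird_id`` and ``sex`` ('F'/'M').

    Returns
    -------
    dict
        Group means/sds/ns, and ``test`` (:class:`TestResult`) or
        ``skipped`` reason.
    """
    quick = metrics[metrics["phase"].isin(QUICK)]
    per_bird = quick.groupby("bird_id", as_index=False)["distance_km"].mean()
    merged = per_bird.merge(sex_table[["bird_id", "sex"]], on="bird_id")
    out: dict = {}
    for sex, g in merged.groupby("sex"):
        out[sex] = {
            "n": int(len(g)),
            "mean_km": float(g["distance_km"].mean()),
            "sd_km": float(g["distance_km"].std(ddof=1)) if len(g) > 1 else float("nan"),
        }
    f = merged.loc[merged["sex"] == "F", "distance_km"]
    m = merged.loc[merged["sex"] == "M", "distance_km"]
    if len(f) < 3 or len(m) < 3:
        out["skipped"] = "need at least 3 birds of each sex"
        return out
    out["test"] = two_sample_t(f, m)
    return out
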