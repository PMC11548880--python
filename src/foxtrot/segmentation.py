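"""Piecewise-regression estimation of migration dates.

Each of the four migration dates (start/end of the fall and spring
migrations) is estimated per bird-season by an exhaustive breakpoint
search: for every candidate BREAK day in a calendar search window, two
independent ordinary-least-squares segments of latitude on day-of-year are
fit (day < BREAK on the left, day >= BREAK on the right; a discontinuity
is allowed), and the BREAK minimising the residual standard error
sqrt(RSS / (n - 4)) wins, ties going to the earliest day. A nested-model
F-test against the single-line fit on the same data slice records whether
the two-segment model is a significant improvement.

The data slice fitted for a date is the search window extended by
``fit_margin`` days on the side *away* from the neighbouring transition
only (before the window for start-type dates, after it for end-type
dates). The fall windows adjoin at one calendar day, so a two-sided
extension would always drag the opposite migration leg into the slice and
bias the fitted break by several days even on noise-free tracks; the
one-sided slice keeps a single structural break in view and recovers
noise-free breakpoints exactly.

The mid-winter turning day — the boundary between the south-westward and
north-eastward halves of the slow phase — is not a regression breakpoint
but simply the day of minimum mean daily latitude between the end of fall
and the start of spring migration (earliest day on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, f_test_nested

__all__ = [
    "SearchWindow",
    "DEFAULT_WINDOWS",
    "SimpleFit",
    "PiecewiseFit",
    "BreakFit",
    "PhaseBounds",
    "fit_simple",
    "fit_piecewise",
    "search_break",
    "winter_turn",
    "estimate_phase_bounds",
    "estimate_population_bounds",
    "summarize_bounds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchWindow:
    """Candidate range for one migration date, on the consecutive-day axis.

    ``extend`` names the side on which ``fit_margin`` days of extra data
    are included in the fitted slice: ``"before"`` for start-type dates
    (the pre-migration plateau/drift lies below the window), ``"after"``
    for end-type dates.
    """

    label: str
    doy_lo: int
    doy_hi: int
    fit_margin: int = 30
    extend: str = "before"

    def __post_init__(self) -> None:
        if not self.doy_lo < self.doy_hi:
            raise ValueError(f"window {self.label}: doy_lo must be < doy_hi")
        if self.fit_margin < 0:
            raise ValueError("fit_margin must be >= 0")
        if self.extend not in ("before", "after"):
            raise ValueError("extend must be 'before' or 'after'")

    @property
    def fit_lo(self) -> int:
        return self.doy_lo - (self.fit_margin if self.extend == "before" else 0)

    @property
    def fit_hi(self) -> int:
        return self.doy_hi + (self.fit_margin if self.extend == "after" else 0)


#: Calendar search windows for the four migration dates (consecutive DOY):
#: fall start 5 Sep - 5 Oct, fall end 5 Oct - 5 Nov, spring start
#: 10 Apr - 10 May, spring end 10 May - 10 Jun.
DEFAULT_WINDOWS = (
    SearchWindow("fall_start", 248, 278, extend="before"),
    SearchWindow("fall_end", 278, 309, extend="after"),
    SearchWindow("spring_start", 465, 495, extend="before"),
    SearchWindow("spring_end", 495, 526, extend="after"),
)


@dataclass(frozen=True)
class SimpleFit:
    slope: float
    intercept: float
    rss: float
    rse: float
    n: int


@dataclass(frozen=True)
class PiecewiseFit:
    break_doy: int
    rss: float
    rse: float
    n: int


@dataclass(frozen=True)
class BreakFit:
    """Best breakpoint for one date, with model-comparison diagnostics."""

    label: str
    break_doy: int
    rse_piecewise: float
    rse_simple: float
    f_stat: float
    p_value: float
    n_obs: int


@dataclass
class PhaseBounds:
    """The five dates splitting one bird-season into Qf/S1/S2/Qs.

    Any field may be None when the track does not cover the corresponding
    search slice (e.g. a tag that died before spring). ``fits`` maps date
    label -> :class:`BreakFit` for the four regression-estimated dates.
    """

    bird_id: str
    season_year: int
    fall_start: int | None = None
    fall_end: int | None = None
    winter_turn: int | None = None
    spring_start: int | None = None
    spring_end: int | None = None

    fits: dict = field(default_factory=dict)

    def ordered(self) -> bool:
        vals = [self.fall_start, self.fall_end, self.winter_turn,
                self.spring_start, self.spring_end]
        present = [v for v in vals if v is not None]
        return all(a < b for a, b in zip(present, present[1:]))

    def complete(self) -> bool:
        return None not in (self.fall_start, self.fall_end, self.winter_turn,
                            self.spring_start, self.spring_end)


def _as_xy(doys, lats) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(doys, dtype=float)
    y = np.asarray(lats, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doys and lats must be 1-D arrays of equal length")
    return x, y


def _ols_rss(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, RSS of a straight-line OLS fit."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("degenerate fit: all day values identical")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    return slope, float(intercept), float(resid @ resid)


def fit_simple(doys: Sequence[float], lats: Sequence[float]) -> SimpleFit:
    """Single-line OLS of latitude on day; RSE = sqrt(RSS / (n - 2)).

    Requires at least 3 points with non-constant day values.
    """
    x, y = _as_xy(doys, lats)
    if x.size < 3:
        raise ValueError(f"simple fit needs >= 3 points, got {x.size}")
    slope, intercept, rss = _ols_rss(x, y)
    return SimpleFit(slope, intercept, rss, float(np.sqrt(rss / (x.size - 2))), int(x.size))


def fit_piecewise(doys: Sequence[float], lats: Sequence[float], break_doy: int) -> PiecewiseFit | None:
    """Two independent OLS segments split at ``break_doy``.

    Left segment takes day < BREAK, right takes day >= BREAK; the two
    lines need not meet (4 parameters). RSE = sqrt(RSS / (n - 4)).

    Returns None when the candidate is infeasible: fewer than 2 points on
    either side, or a side with constant day values.
    """
    x, y = _as_xy(doys, lats)
    left = x < break_doy
    right = ~left
    if left.sum() < 2 or right.sum() < 2:
        return None
    try:
        _, _, rss_l = _ols_rss(x[left], y[left])
        _, _, rss_r = _ols_rss(x[right], y[right])
    except ValueError:
        return None
    n = int(x.size)
    if n <= 4:
        return None
    rss = rss_l + rss_r
    return PiecewiseFit(int(break_doy), rss, float(np.sqrt(rss / (n - 4))), n)


def search_break(daily_track: pd.DataFrame, window: SearchWindow) -> BreakFit:
    """Exhaustive breakpoint search for one migration date.

    Evaluates every integer day in ``[doy_lo, doy_hi]`` on the track's
    data slice (window extended one-sidedly by ``fit_margin``), returns
    the feasible candidate with minimal piecewise RSE (earliest day on
    ties), and attaches the nested F-test of the winning two-segment
    model against the single-line fit on the same slice.

    Raises
    ------
    ValueError
        If the slice is not covered by the track or no candidate is
        feasible.
    """
    sl = daily_track[(daily_track["doy"] >= window.fit_lo) & (daily_track["doy"] <= window.fit_hi)]
    if sl.empty or sl["doy"].min() > window.doy_lo or sl["doy"].max() < window.doy_hi:
        raise ValueError(
            f"track does not cover the {window.label} slice "
            f"[{window.fit_lo}, {window.fit_hi}]"
        )
    x = sl["doy"].to_numpy(dtype=float)
    y = sl["lat"].to_numpy(dtype=float)

    best: PiecewiseFit | None = None
    for b in range(window.doy_lo, window.doy_hi + 1):
        cand = fit_piecewise(x, y, b)
        if cand is None:
            continue
        # ties (to numerical roundoff) resolve to the earliest candidate day
        if best is None or cand.rse < best.rse - 1e-12 * (1.0 + best.rse):
            best = cand
    if best is None:
        raise ValueError(f"no feasible breakpoint in window {window.label}")

    simple = fit_simple(x, y)
    ftest = f_test_nested(simple.rss, 2, best.rss, 4, best.n)
    return BreakFit(
        label=window.label,
        break_doy=best.break_doy,
        rse_piecewise=best.rse,
        rse_simple=simple.rse,
        f_stat=ftest.statistic,
        p_value=ftest.p_value,
        n_obs=best.n,
    )


def winter_turn(daily_track: pd.DataFrame, fall_end: int, spring_start: int) -> int:
    """Day of minimum mean daily latitude between fall end and spring start.

    Ties go to the earliest day.
    """
    sl = daily_track[(daily_track["doy"] >= fall_end) & (daily_track["doy"] <= spring_start)]
    if sl.empty:
        raise ValueError("no positions between fall_end and spring_start")
    sl = sl.sort_values("doy")
    lat = sl["lat"].to_numpy()
    return int(sl["doy"].to_numpy()[int(np.argmin(lat))])


def estimate_phase_bounds(
    daily_track: pd.DataFrame,
    windows: Iterable[SearchWindow] = DEFAULT_WINDOWS,
) -> PhaseBounds:
    """Estimate all five phase-boundary days for one bird-season.

    Dates whose search slice the track does not cover are left None
    (partial result); the winter turn needs both fall_end and
    spring_start. The ordering invariant fall_start < fall_end <
    winter_turn < spring_start < spring_end is checked by the caller via
    :meth:`PhaseBounds.ordered`.
    """
    bird_id = str(daily_track["bird_id"].iloc[0])
    season = int(daily_track["season_year"].iloc[0]) if "season_year" in daily_track else -1
    pb = PhaseBounds(bird_id=bird_id, season_year=season)
    for w in windows:
        try:
            fit = search_break(daily_track, w)
        except ValueError as e:
            logger.info("bird %s: %s", bird_id, e)
            continue
        pb.fits[w.label] = fit
        setattr(pb, w.label, fit.break_doy)
    if pb.fall_end is not None and pb.spring_start is not None:
        try:
            pb.winter_turn = winter_turn(daily_track, pb.fall_end, pb.spring_start)
        except ValueError as e:
            logger.info("bird %s: %s", bird_id, e)
    return pb


def estimate_population_bounds(
    daily: pd.DataFrame,
    windows: Iterable[SearchWindow] = DEFAULT_WINDOWS,
) -> tuple[pd.DataFrame, list[PhaseBounds]]:
    """Per-bird-season boundary estimates for a whole daily-track table.

    Returns
    -------
    bounds : DataFrame
        One row per bird-season that yielded a complete, correctly
        ordered set of dates: the five boundary days plus per-date RSE
        and F-test p-values.
    failures : list of PhaseBounds
        Incomplete or mis-ordered estimates, excluded from summaries
        (each failure is also logged).
    """
    rows = []
    failures: list[PhaseBounds] = []
    for (bird, season), trk in daily.groupby(["bird_id", "season_year"], sort=True):
        pb = estimate_phase_bounds(trk, windows)
        if not (pb.complete() and pb.ordered()):
            logger.warning(
                "bird %s season %s: incomplete or mis-ordered phase bounds, excluded", bird, season
            )
            failures.append(pb)
            continue
        row = {
            "bird_id": pb.bird_id,
            "season_year": pb.season_year,
            "fall_start": pb.fall_start,
            "fall_end": pb.fall_end,
            "winter_turn": pb.winter_turn,
            "spring_start": pb.spring_start,
            "spring_end": pb.spring_end,
        }
        for label, fit in pb.fits.items():
            row[f"{label}_rse"] = fit.rse_piecewise
            row[f"{label}_p"] = fit.p_value
        rows.append(row)
    return pd.DataFrame(rows), failures


def summarize_bounds(bounds: pd.DataFrame, daily: pd.DataFrame) -> pd.DataFrame:
    """Population mean +/- sd of each boundary day, with the mean position
    where birds sit on that day (e.g. where fall migration ended)."""
    recs = []
    merged = daily.merge(bounds[["bird_id", "season_year"]], on=["bird_id", "season_year"])
    for name in ("fall_start", "fall_end", "winter_turn", "spring_start", "spring_end"):
        days = bounds[name]
        pos = merged.merge(
            bounds[["bird_id", "season_year", name]].rename(columns={name: "doy"}),
            on=["bird_id", "season_year", "doy"],
        )
        recs.append(
            {
                "boundary": name,
                "doy_mean": float(days.mean()),
                "doy_sd": float(days.std(ddof=1)) if len(days) > 1 else float("nan"),
                "n": int(days.notna().sum()),
                "lat_mean": float(pos["lat"].mean()) if not pos.empty else float("nan"),
                "lat_sd": float(pos["lat"].std(ddof=1)) if len(pos) > 1 else float("nan"),
                "lon_mean": float(pos["lon"].mean()) if not pos.empty else float("nan"),
                "lon_sd": float(pos["lon"].std(ddof=1)) if len(pos) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(recs)
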