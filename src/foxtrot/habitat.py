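"""Land-cover annotation of daily positions and phase composition.

Positions are annotated by containing-cell lookup in a categorical
land-cover raster (no interpolation — the data are classes; a position on
a shared cell edge goes to the cell with the smaller row, then column
index). Raw satellite land-cover legends are first merged to five
analysis classes — forest (all forest types plus savanna), grassland,
cropland, shrubland, urban — with water bodies and unclassified cells
excluded from all denominators.

Composition is summarised per bird for the pooled quick phases (fall +
spring migration) and the pooled slow phases (both halves of the winter
drift): the percentage of the bird's mean daily positions in each class,
percentages summing to 100 over the non-excluded classes. Quick-vs-slow
differences per class are tested with a paired t on the per-bird share
differences (each bird serves as its own control). Classes annotated for
fewer than ``min_birds_per_class`` birds are flagged rather than tested.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .raster import Raster
from .simulate import LANDCOVER_CODES
from .stats import paired_t

__all__ = [
    "EXCLUDED",
    "RAW_LEGEND",
    "merge_classes",
    "annotate_positions",
    "phase_composition",
]

logger = logging.getLogger(__name__)

#: Sentinel for classes removed from all denominators.
EXCLUDED = "EXCLUDED"

#: Raw legend -> merged analysis class (or EXCLUDED). Already-merged class
#: names map to themselves so merged rasters annotate directly.
RAW_LEGEND: Mapping[str, str] = {
    "forest": "forest",
    "evergreen_needleleaf_forest": "forest",
    "evergreen_broadleaf_forest": "forest",
    "deciduous_needleleaf_forest": "forest",
    "deciduous_broadleaf_forest": "forest",
    "savanna": "forest",
    "grassland": "grassland",
    "cropland": "cropland",
    "shrubland": "shrubland",
    "urban": "urban",
    "water": EXCLUDED,
    "unclassified": EXCLUDED,
}

QUICK_PHASES = ("Qf", "Qs")
SLOW_PHASES = ("S1", "S2")


def merge_classes(raw_class: str) -> str:
    """Map a raw legend class to its merged analysis class or EXCLUDED.

    Already-merged class names pass through unchanged.

    Raises
    ------
    ValueError
        For a class absent from the legend; the error lists the legend.
    """
    if raw_class in RAW_LEGEND:
        return RAW_LEGEND[raw_class]
    raise ValueError(
        f"unknown land-cover class {raw_class!r}; legend: {sorted(RAW_LEGEND)}"
    )


def annotate_positions(landcover: Raster, daily: pd.DataFrame) -> pd.DataFrame:
    """Attach a land-cover class to each daily position.

    Containing-cell lookup; positions outside the raster extent are
    dropped with a logged count. The returned frame adds a ``landcover``
    column of merged class names (EXCLUDED rows retained here — they are
    removed from denominators downstream).
    """
    rows, cols = landcover.cell_index(daily["lat"].to_numpy(), daily["lon"].to_numpy())
    ok = rows >= 0
    if (~ok).any():
        logger.warning("dropped %d positions outside the land-cover raster", int((~ok).sum()))
    out = daily.loc[ok].reset_index(drop=True).copy()
    codes = landcover.values[rows[ok], cols[ok]].astype(int)
    out["landcover"] = [merge_classes(LANDCOVER_CODES[c]) for c in codes]
    return out


def _phase_group(doy: np.ndarray, b: pd.Series | dict) -> np.ndarray:
    """'quick' / 'slow' / '' per day, from one bird-season's bounds.

    Quick covers [fall_start, fall_end] and [spring_start, spring_end];
    slow covers the open interval between the fall end and spring start.
    """
    group = np.full(doy.shape, "", dtype=object)
    quick = ((doy >= b["fall_start"]) & (doy <= b["fall_end"])) | (
        (doy >= b["spring_start"]) & (doy <= b["spring_end"])
    )
    slow = (doy > b["fall_end"]) & (doy < b["spring_start"])
    group[quick] = "quick"
    group[slow] = "slow"
    return group


def phase_composition(
    annotated: pd.DataFrame,
    bounds: pd.DataFrame,
    min_birds_per_class: int = 5,
) -> dict:
    """Per-bird and population land-cover composition of quick vs slow phases.

    Parameters
    ----------
    annotated : DataFrame
        Daily positions with a ``landcover`` column
        (:func:`annotate_positions` output).
    bounds : DataFrame
        Per-bird-season phase bounds.
    min_birds_per_class : int
        Classes annotated for fewer birds than this (in either group) are
        flagged and not tested.

    Returns
    -------
    dict with keys
        ``per_bird`` — bird x phase-group x class percentages (summing to
        100 per bird-group over non-excluded classes);
        ``summary`` — population mean +/- sd percent per class and group;
        ``contrasts`` — per-class paired quick-minus-slow share test
        (``flagged`` instead of a test where too few birds).
    """
    merged = annotated.merge(
        bounds[["bird_id", "season_year", "fall_start", "fall_end", "spring_start", "spring_end"]],
        on=["bird_id", "season_year"],
    )
    merged["phase_group"] = ""
    for key, g in merged.groupby(["bird_id", "season_year"]):
        b = g.iloc[0]
        merged.loc[g.index, "phase_group"] = _phase_group(g["doy"].to_numpy(), b)
    merged = merged[(merged["phase_group"] != "") & (merged["landcover"] != EXCLUDED)]
    n_excluded = int((annotated["landcover"] == EXCLUDED).sum())
    if n_excluded:
        logger.info("excluded %d positions on water/unclassified cells", n_excluded)

    counts = (
        merged.groupby(["bird_id", "phase_group", "landcover"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(["bird_id", "phase_group"])["n"].transform("sum")
    counts["pct"] = 100.0 * counts["n"] / totals

    classes = sorted(set(LANDCOVER_CODES.values()))
    per_bird = (
        counts.pivot_table(
            index=["bird_id", "phase_group"], columns="landcover", values="pct", fill_value=0.0
        )
        .reindex(columns=classes, fill_value=0.0)
        .reset_index()
    )

    summary_rows = []
    contrasts: dict[str, object] = {}
    for cls in classes:
        for group in ("quick", "slow"):
            vals = per_bird.loc[per_bird["phase_group"] == group, cls]
            present = counts[
                (counts["phase_group"] == group) & (counts["landcover"] == cls)
            ]["bird_id"].nunique()
            summary_rows.append(
                {
                    "landcover": cls,
                    "phase_group": group,
                    "mean_pct": float(vals.mean()) if len(vals) else float("nan"),
                    "sd_pct": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n_birds": int(present),
                }
            )
        wide = per_bird.pivot_table(index="bird_id", columns="phase_group", values=cls)
        if not {"quick", "slow"} <= set(wide.columns):
            contrasts[cls] = {"flagged": "missing a phase group"}
            continue
        paired = wide[["quick", "slow"]].dropna()
        n_annotated = min(
            counts[(counts["phase_group"] == g) & (counts["landcover"] == cls)]["bird_id"].nunique()
            for g in ("quick", "slow")
        )
        if n_annotated < min_birds_per_class:
            contrasts[cls] = {
                "flagged": f"annotated for {n_annotated} birds (< {min_birds_per_class})"
            }
            continue
        diffs = (paired["quick"] - paired["slow"]).to_numpy()
        contrasts[cls] = paired_t(diffs)

    return {
        "per_bird": per_bird,
        "summary": pd.DataFrame(summary_rows),
        "contrasts": contrasts,
    }
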