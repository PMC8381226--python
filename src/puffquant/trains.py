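"""Temporal-summation analysis of puff-train responses.

Train responses are summarised per cell and puff count (mean area over
the five trials of a condition), normalised within each cell to its own
1-puff mean, averaged across cells, and the across-cell mean normalized
responses are fit with an ordinary least-squares line over the puff
counts.  The summation ratio (10-puff over 1-puff response) quantifies
the net gain of a full train.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LineFit",
    "normalize_train_responses",
    "condition_mean_normalized",
    "fit_mean_line",
    "summation_ratio",
    "analyze_trains",
]

REQUIRED_COLUMNS = ("cell_id", "puff_count", "mean_area")


@dataclass(frozen=True)
class LineFit:
    """Ordinary least-squares line: slope, intercept and Pearson r."""

    slope: float
    intercept: float
    pearson_r: float


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"summation table lacks columns {missing}")


def normalize_train_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each cell's responses by that cell's own 1-puff mean.

    ``table`` needs columns ``cell_id``, ``puff_count`` and
    ``mean_area`` (one row per cell x puff count; extra columns pass
    through).  Adds/overwrites ``normalized_area``.  Every cell must
    have a positive 1-puff mean; the operation is idempotent because the
    normalized 1-puff value is exactly 1.
    """
    _check_table(table)
    out = table.copy()
    denom = {}
    for cell, grp in out.groupby("cell_id"):
        one = grp.loc[grp["puff_count"] == 1, "mean_area"]
        if one.empty:
            raise ValueError(f"cell {cell!r} has no 1-puff measurement")
        val = float(one.mean())
        if val <= 0:
            raise ValueError(
                f"cell {cell!r} has a non-positive 1-puff response ({val:g}); "
                "cannot normalize"
            )
        denom[cell] = val
    out["normalized_area"] = out["mean_area"] / out["cell_id"].map(denom)
    return out


def condition_mean_normalized(table: pd.DataFrame) -> pd.DataFrame:
    """Across-cell mean (and SD) of the normalized areas per puff count."""
    if "normalized_area" not in table.columns:
        table = normalize_train_responses(table)
    g = table.groupby("puff_count")["normalized_area"]
    return pd.DataFrame(
        {
            "puff_count": g.mean().index,
            "mean_normalized": g.mean().to_numpy(),
            "sd_normalized": g.std(ddof=1).to_numpy(),
            "n_cells": g.count().to_numpy(),
        }
    ).reset_index(drop=True)


def fit_mean_line(puff_counts: np.ndarray, means: np.ndarray) -> LineFit:
    """OLS line through the (puff count, across-cell mean) points."""
    x = np.asarray(puff_counts, dtype=float)
    y = np.asarray(means, dtype=float)
    if x.shape != y.shape:
        raise ValueError("puff_counts and means must have equal length")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct puff counts for a line fit")
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    return LineFit(slope=float(slope), intercept=float(intercept), pearson_r=r)


def summation_ratio(table: pd.DataFrame, at_count: int = 10) -> float:
    """Across-cell mean normalized response at ``at_count`` puffs.

    With per-cell normalization this equals the mean 10-puff/1-puff
    area ratio.
    """
    if "normalized_area" not in table.columns:
        table = normalize_train_responses(table)
    counts = set(table["puff_count"].unique())
    for needed in (1, at_count):
        if needed not in counts:
            raise ValueError(f"table has no {needed}-puff measurements")
    sel = table.loc[table["puff_count"] == at_count, "normalized_area"]
    return float(sel.mean())


def analyze_trains(table: pd.DataFrame) -> dict:
    """Normalize, average, fit and ratio one condition's summation table.

    Returns a dict with the normalized table, the per-count means, the
    :class:`LineFit` to the means, and the 10-puff summation ratio (NaN
    when the table has no 10-puff trains).
    """
    norm = normalize_train_responses(table)
    means = condition_mean_normalized(norm)
    fit = fit_mean_line(
        means["puff_count"].to_numpy(), means["mean_normalized"].to_numpy()
    )
    try:
        ratio = summation_ratio(norm)
    except ValueError:
        ratio = float("nan")
    return {"table": norm, "means": means, "fit": fit, "ratio_10_1": ratio}
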