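"""Estimation of model inputs from in-vitro measurement tables.

Turns the three raw assay tables — daily hemocytometer cell counts,
per-cell segmented areas, and per-replicate spheroid areas — into the
quantities the simulator is parameterized with: doubling time (log-linear
regression), mean cell diameter (equivalent-circle average) and
growth-curve mean +/- SD statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DoublingTimeEstimate",
    "DataError",
    "DegenerateGrowthError",
    "estimate_doubling_time",
    "average_cell_diameter",
    "growth_curve_stats",
    "estimate_parameters",
]

CELL_COUNT_COLUMNS = ["line", "day", "count_per_ml"]
CELL_AREA_COLUMNS = ["line", "cell_id", "area_um2"]
SPHEROID_AREA_COLUMNS = ["line", "day", "replicate", "area_mm2"]


class DataError(ValueError):
    """Malformed or physically impossible measurement data."""


class DegenerateGrowthError(ValueError):
    """Cell counts show no exponential growth (slope <= 0)."""


@dataclass(frozen=True)
class DoublingTimeEstimate:
    dt_h: float
    sd_h: float
    slope_per_h: float
    n_points: int


def estimate_doubling_time(
    days: Sequence[float],
    counts: Sequence[float],
    method: str = "loglinear",
) -> DoublingTimeEstimate:
    """Doubling time from a daily count series.

    ``loglinear`` (default): ordinary least squares of ln(count) on time
    in hours; dt = ln 2 / slope, with the SD propagated from the slope's
    standard error by the delta method. ``nonlinear`` fits
    N0 * 2^(t/dt) directly (sensitivity option).
    """
    days = np.asarray(days, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if days.shape != counts.shape or days.ndim != 1:
        raise DataError("days and counts must be 1D arrays of equal length")
    if np.unique(days).size < 3:
        raise DataError(f"need >= 3 distinct days, got {np.unique(days).size}")
    if np.any(counts <= 0) or not np.all(np.isfinite(counts)):
        raise DataError("counts must be positive and finite")
    hours = days * 24.0

    if method == "loglinear":
        fit = stats.linregress(hours, np.log(counts))
        slope, se = fit.slope, fit.stderr
    elif method == "nonlinear":
        from scipy.optimize import curve_fit

        start = stats.linregress(hours, np.log(counts))
        if start.slope <= 0:
            raise DegenerateGrowthError(
                f"no exponential growth: log-linear slope {start.slope:.3g} <= 0"
            )
        p0 = (counts[0], start.slope / np.log(2))
        popt, pcov = curve_fit(
            lambda t, n0, g: n0 * np.power(2.0, g * t), hours, counts, p0=p0
        )
        slope = popt[1] * np.log(2)
        se = float(np.sqrt(pcov[1, 1])) * np.log(2)
    else:
        raise ValueError(f"unknown method {method!r}")

    if slope <= 0:
        raise DegenerateGrowthError(f"no exponential growth: slope {slope:.3g} <= 0")
    dt_h = np.log(2) / slope
    sd_h = np.log(2) * se / slope**2 if np.isfinite(se) else 0.0
    return DoublingTimeEstimate(
        dt_h=float(dt_h), sd_h=float(sd_h), slope_per_h=float(slope),
        n_points=len(days),
    )


def average_cell_diameter(areas_um2: Sequence[float]) -> float:
    """Mean equivalent-circle diameter (um) of segmented cell areas."""
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size == 0:
        raise DataError("no cell areas supplied")
    if np.any(areas <= 0) or not np.all(np.isfinite(areas)):
        raise DataError("cell areas must be positive and finite")
    return float(np.mean(2.0 * np.sqrt(areas / np.pi)))


def growth_curve_stats(spheroid_table: pd.DataFrame) -> pd.DataFrame:
    """Per (line, day) mean and sample SD (ddof=1) of spheroid areas.

    Days with a single replicate get SD 0 with a logged caveat.
    """
    missing = [c for c in SPHEROID_AREA_COLUMNS if c not in spheroid_table.columns]
    if missing:
        raise DataError(f"spheroid table missing columns {missing}")
    if spheroid_table.empty:
        raise DataError("spheroid table is empty")
    g = spheroid_table.groupby(["line", "day"])["area_mm2"]
    out = g.agg(mean_area_mm2="mean", sd_area_mm2="std", n_replicates="count")
    singles = out["n_replicates"] == 1
    if singles.any():
        logger.warning(
            "SD reported as 0 for %d (line, day) groups with a single replicate",
            int(singles.sum()),
        )
    out["sd_area_mm2"] = out["sd_area_mm2"].fillna(0.0)
    return out.reset_index()


def estimate_parameters(
    cell_counts: pd.DataFrame,
    cell_areas: pd.DataFrame,
    method: str = "loglinear",
    include_day0: bool = True,
) -> pd.DataFrame:
    """Per-line parameter table (line, diameter_um, dt_h, dt_sd_h).

    ``include_day0=False`` drops the seeded day-0 count from the
    regression (pre-attachment count option). When a line has multiple
    count series only the pooled fit is reported.
    """
    for df, cols, name in (
        (cell_counts, CELL_COUNT_COLUMNS, "cell_counts"),
        (cell_areas, CELL_AREA_COLUMNS, "cell_areas"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DataError(f"{name} table missing columns {missing}")
    rows = []
    lines = sorted(set(cell_counts["line"]) | set(cell_areas["line"]))
    for line in lines:
        counts = cell_counts[cell_counts["line"] == line]
        if not include_day0:
            counts = counts[counts["day"] > 0]
        areas = cell_areas[cell_areas["line"] == line]
        row = {"line": line, "diameter_um": np.nan, "dt_h": np.nan, "dt_sd_h": np.nan}
        if len(counts):
            est = estimate_doubling_time(counts["day"], counts["count_per_ml"], method)
            row["dt_h"], row["dt_sd_h"] = est.dt_h, est.sd_h
        if len(areas):
            row["diameter_um"] = average_cell_diameter(areas["area_um2"])
        rows.append(row)
    return pd.DataFrame(rows)
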