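"""Parameter-study and clonal-competition drivers with replicate statistics.

Three monoclonal sweeps (doubling time, cell size, proliferation depth)
read out the mean day-10 area over seeded replicates and the relative
increases between consecutive parameter values. The polyclonal driver
seeds many clones differing only in doubling time and tracks both the
area expansion and the doubling-time envelope of the surviving clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lattice import Phenotype
from .simulate import GrowthRecord, SimulationConfig, run

__all__ = [
    "SweepResult",
    "PolyclonalResult",
    "relative_increase",
    "run_replicates",
    "sweep_doubling_time",
    "sweep_cell_size",
    "sweep_depth",
    "polyclonal_run",
]

DT_SWEEP_VALUES = (15.5, 20.5, 25.5, 30.5, 35.5)
CELL_SIZE_SWEEP_VALUES = (14.0, 16.0, 18.0, 20.0)
DEPTH_SWEEP_VALUES = (1, 2, 3, 4, 5)
POLYCLONAL_DT_INTERVAL = (15.5, 35.5)


def relative_increase(a_low: float, a_high: float) -> float:
    """Percent increase of ``a_high`` over ``a_low``: 100*(a_high - a_low)/a_low."""
    if a_low <= 0:
        raise ValueError(f"reference area must be > 0, got {a_low}")
    return 100.0 * (a_high - a_low) / a_low


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate integer seeds (< 2**31) from a master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def run_replicates(config: SimulationConfig, reps: int, seed: int) -> List[GrowthRecord]:
    seeds = spawn_seeds(seed, reps)
    return [run(config.with_(seed=int(s))) for s in seeds]


@dataclass
class SweepResult:
    """One-parameter monoclonal sweep summary.

    ``increases`` holds, for each consecutive pair of parameter values
    (ordered from the slower-growing to the faster-growing condition),
    the percent increase of the mean day-10 area, recomputable from
    ``day10_mean_areas``.
    """

    parameter: str
    values: Tuple[float, ...]
    time_days: np.ndarray
    mean_curves: np.ndarray           # (n_values, n_times)
    day10_areas: np.ndarray           # (n_values, reps)
    day10_mean_areas: np.ndarray      # (n_values,)
    increases: List[Tuple[float, float, float]]  # (value_low_area, value_high_area, pct)
    reference_day: float = 10.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, areas in zip(self.values, self.day10_areas):
            for rep, a in enumerate(areas):
                rows.append(
                    {self.parameter: v, "replicate": rep,
                     f"day{self.reference_day:g}_area_mm2": a}
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        inc_by_pair = {(lo, hi): pct for lo, hi, pct in self.increases}
        rows = []
        for i, v in enumerate(self.values):
            rows.append(
                {
                    self.parameter: v,
                    "mean_day10_area_mm2": self.day10_mean_areas[i],
                    "sd_day10_area_mm2": float(np.std(self.day10_areas[i], ddof=1)),
                }
            )
        df = pd.DataFrame(rows)
        df["pct_increase_vs_prev"] = [np.nan] + [
            inc_by_pair.get((self.values[i - 1], self.values[i]))
            or inc_by_pair.get((self.values[i], self.values[i - 1]))
            for i in range(1, len(self.values))
        ]
        return df


def _sweep(
    parameter: str,
    configs: Sequence[SimulationConfig],
    values: Sequence[float],
    reps: int,
    seed: int,
    reference_day: float,
    faster_is_later: bool,
) -> SweepResult:
    """Run the replicate grid and compute consecutive relative increases.

    ``faster_is_later``: whether growth increases with the parameter value
    (cell size, depth) or decreases (doubling time); the increase is always
    reported as faster-over-slower.
    """
    all_day10 = []
    mean_curves = []
    time_days = None
    for cfg in configs:
        recs = run_replicates(cfg, reps, seed)
        time_days = recs[0].time_days
        mean_curves.append(np.mean([r.area_mm2 for r in recs], axis=0))
        all_day10.append([r.area_at_day(reference_day) for r in recs])
    day10 = np.asarray(all_day10)
    means = day10.mean(axis=1)
    increases = []
    for i in range(1, len(values)):
        if faster_is_later:
            a_low, a_high = means[i - 1], means[i]
        else:
            a_low, a_high = means[i], means[i - 1]
        increases.append((float(a_low), float(a_high), relative_increase(a_low, a_high)))
    return SweepResult(
        parameter=parameter,
        values=tuple(values),
        time_days=time_days,
        mean_curves=np.asarray(mean_curves),
        day10_areas=day10,
        day10_mean_areas=means,
        increases=increases,
        reference_day=reference_day,
    )


def sweep_doubling_time(
    base_config: Optional[SimulationConfig] = None,
    dt_values: Sequence[float] = DT_SWEEP_VALUES,
    reps: int = 20,
    seed: int = 0,
    reference_day: float = 10.0,
) -> SweepResult:
    """Monoclonal doubling-time sweep (cell size 18 um, depth 2 by default).

    Increases are reported faster-over-slower, i.e. for consecutive dt
    values the percent gain obtained by lowering the doubling time.
    """
    base = base_config or SimulationConfig()
    depth = base.phenotypes[0].proliferation_depth_r
    configs = [
        base.with_(phenotypes=(Phenotype(0, float(dt), depth),)) for dt in dt_values
    ]
    return _sweep("doubling_time_h", configs, dt_values, reps, seed,
                  reference_day, faster_is_later=False)


def sweep_cell_size(
    base_config: Optional[SimulationConfig] = None,
    sizes_um: Sequence[float] = CELL_SIZE_SWEEP_VALUES,
    reps: int = 20,
    seed: int = 0,
    reference_day: float = 10.0,
) -> SweepResult:
    """Monoclonal cell-size sweep at doubling time 25.5 h, depth 2."""
    base = base_config or SimulationConfig(phenotypes=(Phenotype(0, 25.5, 2),))
    configs = [base.with_(cell_size_um=float(h)) for h in sizes_um]
    return _sweep("cell_size_um", configs, sizes_um, reps, seed,
                  reference_day, faster_is_later=True)


def sweep_depth(
    base_config: Optional[SimulationConfig] = None,
    depths: Sequence[int] = DEPTH_SWEEP_VALUES,
    reps: int = 20,
    seed: int = 0,
    reference_day: float = 10.0,
) -> SweepResult:
    """Monoclonal proliferation-depth sweep at doubling time 25.5 h, 18 um."""
    base = base_config or SimulationConfig(phenotypes=(Phenotype(0, 25.5, 2),))
    dt = base.phenotypes[0].doubling_time_h
    configs = [base.with_(phenotypes=(Phenotype(0, dt, int(r)),)) for r in depths]
    return _sweep("proliferation_depth_r", configs, depths, reps, seed,
                  reference_day, faster_is_later=True)


@dataclass
class PolyclonalResult:
    """Clonal-competition scenario summary over replicates.

    Doubling-time envelope statistics (min/max/mean over the clones
    still alive at each time) are reported as mean and SD across the
    replicates; replicates where every clone died contribute NaN.
    """

    n_phenotypes: int
    reps: int
    time_days: np.ndarray
    area_curves: np.ndarray            # (reps, n_times)
    mean_area: np.ndarray
    sd_area: np.ndarray
    min_dt: np.ndarray                 # (reps, n_times), per-time surviving min
    max_dt: np.ndarray
    mean_dt: np.ndarray                # unweighted mean over surviving clones
    weighted_mean_dt: np.ndarray       # cell-count-weighted mean doubling time

    @property
    def mean_min_dt(self) -> np.ndarray:
        return np.nanmean(self.min_dt, axis=0)

    @property
    def mean_max_dt(self) -> np.ndarray:
        return np.nanmean(self.max_dt, axis=0)

    @property
    def mean_mean_dt(self) -> np.ndarray:
        return np.nanmean(self.mean_dt, axis=0)

    @property
    def sd_min_dt(self) -> np.ndarray:
        return np.nanstd(self.min_dt, axis=0, ddof=1)

    @property
    def mean_weighted_dt(self) -> np.ndarray:
        return np.nanmean(self.weighted_mean_dt, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep in range(self.reps):
            rows.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "time_days": self.time_days,
                        "area_mm2": self.area_curves[rep],
                        "min_surviving_dt_h": self.min_dt[rep],
                        "max_surviving_dt_h": self.max_dt[rep],
                        "mean_surviving_dt_h": self.mean_dt[rep],
                        "weighted_mean_dt_h": self.weighted_mean_dt[rep],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def polyclonal_run(
    base_config: Optional[SimulationConfig] = None,
    n_phenotypes: int = 100,
    reps: int = 50,
    seed: int = 0,
    duration_days: float = 14.0,
    dt_interval: Tuple[float, float] = POLYCLONAL_DT_INTERVAL,
) -> PolyclonalResult:
    """Competition between clones differing only in doubling time.

    Per replicate, ``n_phenotypes`` doubling times are drawn i.i.d.
    uniform on ``dt_interval`` and assigned uniformly to the seeded
    cells (cell size 18 um, depth 2 by default); each replicate runs
    ``duration_days`` simulated days.
    """
    if n_phenotypes < 1:
        raise ValueError(f"n_phenotypes must be >= 1, got {n_phenotypes}")
    base = base_config or SimulationConfig()
    base = base.with_(duration_days=duration_days)
    depth = base.phenotypes[0].proliferation_depth_r
    seeds = spawn_seeds(seed, reps)
    draw_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    area_curves, min_dt, max_dt, mean_dt, weighted_dt = [], [], [], [], []
    time_days = None
    for s in seeds:
        dts = draw_rng.uniform(dt_interval[0], dt_interval[1], size=n_phenotypes)
        phens = tuple(Phenotype(i, float(dt), depth) for i, dt in enumerate(dts))
        rec = run(base.with_(phenotypes=phens, seed=int(s)))
        time_days = rec.time_days
        area_curves.append(rec.area_mm2)
        counts = np.stack([rec.phenotype_counts[p.id] for p in phens])  # (P, T)
        alive = counts > 0
        dt_col = dts[:, None] * np.ones(counts.shape[1])
        masked = np.where(alive, dt_col, np.nan)
        with np.errstate(invalid="ignore"):
            min_dt.append(np.nanmin(masked, axis=0))
            max_dt.append(np.nanmax(masked, axis=0))
            mean_dt.append(np.nanmean(masked, axis=0))
        totals = counts.sum(axis=0)
        weighted_dt.append(
            np.where(totals > 0, (dts[:, None] * counts).sum(axis=0) / totals, np.nan)
        )

    return PolyclonalResult(
        n_phenotypes=n_phenotypes,
        reps=reps,
        time_days=time_days,
        area_curves=np.asarray(area_curves),
        mean_area=np.mean(area_curves, axis=0),
        sd_area=np.std(area_curves, axis=0, ddof=1),
        min_dt=np.asarray(min_dt),
        max_dt=np.asarray(max_dt),
        mean_dt=np.asarray(mean_dt),
        weighted_mean_dt=np.asarray(weighted_dt),
    )
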