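"""Synthetic in-vitro-shaped data with known ground truth.

Emulates the structure of the three measurement tables the estimation
stage consumes — daily cell counts (exponential growth with
multiplicative log-normal noise), per-cell segmented areas (truncated
normal diameters) and replicate spheroid growth curves (simulator
output plus additive Gaussian noise) — so estimation and calibration
can be validated by parameter recovery without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SimulationConfig, run

__all__ = ["SynthSpec", "gen_cell_counts", "gen_cell_areas", "gen_observed_growth"]


@dataclass(frozen=True)
class SynthSpec:
    """Ground-truth parameters for the synthetic generators.

    Count noise is multiplicative log-normal with median 1 (counts are
    positive and hemocytometer error scales with the count); area noise
    is additive Gaussian on the area.
    """

    line: str = "SYNTH"
    dt_h: float = 30.8
    n0_per_ml: float = 20000.0
    days: int = 7
    count_cv: float = 0.10
    diameter_um: float = 18.0
    diameter_cv: float = 0.10
    n_cells: int = 10
    sim_config: Optional[SimulationConfig] = None
    area_cv: float = 0.05
    n_replicates: int = 24
    sample_interval_days: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise ValueError(f"dt_h must be > 0, got {self.dt_h}")
        if self.n0_per_ml <= 0:
            raise ValueError(f"n0_per_ml must be > 0, got {self.n0_per_ml}")
        if self.days < 3:
            raise ValueError(f"days must be >= 3, got {self.days}")
        for name in ("count_cv", "diameter_cv", "area_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.diameter_um <= 0 or self.n_cells < 1 or self.n_replicates < 1:
            raise ValueError("diameter_um, n_cells, n_replicates must be positive")
        if self.sample_interval_days <= 0:
            raise ValueError("sample_interval_days must be > 0")

    def ground_truth(self) -> dict:
        d = asdict(self)
        if self.sim_config is not None:
            d["sim_config"] = {
                "cell_size_um": self.sim_config.cell_size_um,
                "tau_h": self.sim_config.tau_h,
                "duration_days": self.sim_config.duration_days,
                "initial_cells": self.sim_config.initial_cells,
                "doubling_times_h": [p.doubling_time_h for p in self.sim_config.phenotypes],
                "depths": [p.proliferation_depth_r for p in self.sim_config.phenotypes],
                "seed": self.sim_config.seed,
            }
        return d


def gen_cell_counts(spec: SynthSpec) -> pd.DataFrame:
    """Daily count series: N0 * 2^(24 d / dt) * eps, eps log-normal, median 1."""
    rng = np.random.default_rng(spec.seed)
    day = np.arange(spec.days + 1)
    ideal = spec.n0_per_ml * 2.0 ** (24.0 * day / spec.dt_h)
    if spec.count_cv > 0:
        sigma = np.sqrt(np.log1p(spec.count_cv**2))
        eps = np.exp(rng.normal(0.0, sigma, size=day.size))
    else:
        eps = np.ones(day.size)
    return pd.DataFrame(
        {"line": spec.line, "day": day, "count_per_ml": ideal * eps}
    )


def gen_cell_areas(spec: SynthSpec) -> pd.DataFrame:
    """Segmented single-cell areas from truncated-normal diameters."""
    rng = np.random.default_rng(spec.seed)
    sd = spec.diameter_cv * spec.diameter_um
    if sd == 0:
        d = np.full(spec.n_cells, spec.diameter_um)
    else:
        a = (0.0 - spec.diameter_um) / sd  # truncate at 0: diameters stay positive
        d = stats.truncnorm.rvs(
            a, np.inf, loc=spec.diameter_um, scale=sd,
            size=spec.n_cells, random_state=rng,
        )
    return pd.DataFrame(
        {
            "line": spec.line,
            "cell_id": np.arange(spec.n_cells),
            "area_um2": np.pi * (d / 2.0) ** 2,
        }
    )


def gen_observed_growth(spec: SynthSpec) -> Tuple[pd.DataFrame, dict]:
    """Replicate spheroid-area table from a simulated growth curve.

    Runs the simulator once per the embedded config, samples the curve
    at the observation interval and adds i.i.d. additive Gaussian noise
    (SD = area_cv x area) per replicate. Returns the tidy table plus the
    generating ground truth.
    """
    if spec.sim_config is None:
        raise ValueError("spec.sim_config is required for gen_observed_growth")
    rng = np.random.default_rng(spec.seed)
    rec = run(spec.sim_config)
    days = np.arange(0.0, spec.sim_config.duration_days + 1e-9,
                     spec.sample_interval_days)
    ideal = np.interp(days, rec.time_days, rec.area_mm2)
    rows = []
    for rep in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.area_cv * ideal) if spec.area_cv > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {
                    "line": spec.line,
                    "day": days,
                    "replicate": rep,
                    "area_mm2": ideal + noise,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    truth = spec.ground_truth()
    truth["noiseless_curve"] = {"day": days.tolist(), "area_mm2": ideal.tolist()}
    return table, truth
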