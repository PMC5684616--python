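"""Figure helpers: area-vs-time curves and doubling-time envelopes."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .experiments import PolyclonalResult, SweepResult

__all__ = ["plot_sweep", "plot_polyclonal_envelope"]


def plot_sweep(result: SweepResult, path: Union[str, Path]) -> Path:
    """Mean area-vs-time curves, one line per swept parameter value."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for value, curve in zip(result.values, result.mean_curves):
        ax.plot(result.time_days, curve, label=f"{result.parameter} = {value:g}")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("spheroid area (mm$^2$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_polyclonal_envelope(
    result: PolyclonalResult, path: Union[str, Path],
    title: Optional[str] = None,
) -> Path:
    """Mean min/mean/max surviving doubling time over time, +/- SD band for the min."""
    fig, ax = plt.subplots(figsize=(6, 4))
    t = result.time_days
    ax.plot(t, result.mean_min_dt, label="mean min dt")
    ax.plot(t, result.mean_mean_dt, label="mean dt")
    ax.plot(t, result.mean_max_dt, label="mean max dt")
    ax.fill_between(
        t,
        result.mean_min_dt - result.sd_min_dt,
        result.mean_min_dt + result.sd_min_dt,
        alpha=0.2,
    )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("surviving doubling time (h)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
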