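"""Basic figure regeneration: seasonal dynamics bands and sweep curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .simulate import EnsembleResult

__all__ = ["plot_dynamics", "plot_sweep"]


def plot_dynamics(result: EnsembleResult, path: str | Path) -> Path:
    """Median host/parasitoid densities with interquartile band, plus the
    three parasitism measures, over the season."""
    d = result.daily
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    ax1.fill_between(d["day"], d["N_q25"], d["N_q75"], color="0.8", label="IQR")
    ax1.plot(d["day"], d["N_median"], "k-", label="host (living aphids)")
    ax1.plot(d["day"], d["parasitoid_total_median"], "k--", label="parasitoid (all stages)")
    ax1.axhline(result.config_ET, ls=":", color="k", lw=0.8, label="economic threshold")
    ax1.set_ylabel("density (per plant)")
    ax1.set_yscale("log")
    ax1.legend(frameon=False, fontsize=8)
    ax2.plot(d["day"], d["rate_median"], "k-", label="parasitism rate (1/d)")
    ax2.plot(d["day"], d["percent_parasitism_median"] / 100.0, "k--", label="parasitism fraction")
    ax2.plot(d["day"], d["mummy_fraction_median"], "k:", label="mummy fraction")
    ax2.set_xlabel("day of simulation")
    ax2.set_ylabel("parasitism measure")
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_sweep(df: pd.DataFrame, x: str, path: str | Path, xlabel: str | None = None) -> Path:
    """One sweep curve: peak pest reduction vs the swept parameter."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(df[x], df["peak_reduction_pct"], "k-o", ms=3)
    ax.set_xlabel(xlabel or x)
    ax.set_ylabel("peak pest reduction (%)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
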