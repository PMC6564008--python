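"""Sensitivity sweeps and model variants.

Four one-dimensional sweeps probe how peak pest reduction responds to
adult parasitoid lifespan, parasitoid colonization date, host-stage
preference, and mean daily temperature.  Each sweep runs single paired
simulations (with/without parasitoid) at the median initial densities of
the field-season protocol, holding everything else at the defaults.

Two variants are provided: exclusion of post-parasitism reproduction
(J_i = 0), and the decreasing-r model in which the host projection matrix
is damped by lambda_A**(-a*t) to emulate declining plant quality over the
season.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import core
from .params import ModelParameters, ParameterError
from .simulate import SimulationConfig, Trajectory, peak_reduction, run_ensemble, run_simulation
from .weather import TemperatureSeries

__all__ = [
    "DecreasingRParams",
    "dominant_eigenvalue",
    "decreasing_r_step",
    "preference_grid",
    "sweep_lifespan",
    "sweep_colonization",
    "sweep_preference",
    "sweep_temperature",
    "exclusion_experiment",
]

JUVENILE_ANCHOR = (0.50, 0.35, 0.10, 0.05, 0.00)
UNIFORM_PREFERENCE = (0.2, 0.2, 0.2, 0.2, 0.2)
ADULT_ANCHOR = (0.00, 0.05, 0.10, 0.35, 0.50)

#: seasonal decline rate of the host intrinsic growth rate (1/d)
DEFAULT_DECLINE_RATE = 0.0247


@dataclass(frozen=True)
class DecreasingRParams:
    """Decreasing-r variant settings: daily decline rate of r."""

    a_dr: float = DEFAULT_DECLINE_RATE

    def __post_init__(self) -> None:
        if self.a_dr < 0:
            raise ParameterError(f"decline rate must be >= 0; got {self.a_dr!r}")


def dominant_eigenvalue(A: np.ndarray) -> float:
    """Spectral radius of a non-negative projection matrix (the finite
    rate of increase lambda for the primitive host matrix)."""
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("projection matrix must be non-negative")
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def decreasing_r_step(
    state: core.PopulationState,
    A: np.ndarray,
    H: np.ndarray,
    C_sba: np.ndarray,
    hp,
    drp: DecreasingRParams,
    t: int,
    recruits: float = 0.0,
    lam_A: float | None = None,
) -> np.ndarray:
    """Host step with the projection matrix damped by lambda_A**(-a*t).

    ``t`` counts days since host colonization; at t = 0 (or a = 0) the
    step coincides with :func:`hpmatrix.core.host_step`.
    """
    if lam_A is None:
        lam_A = dominant_eigenvalue(A)
    damping = lam_A ** (-drp.a_dr * t)
    return core.host_step(state, A, H, C_sba, hp, recruits, damping)


def _paired_reduction(
    cfg: SimulationConfig,
    params: ModelParameters,
    temps: TemperatureSeries,
) -> float:
    """Peak reduction of a single paired run at median initial densities."""
    with_traj = run_simulation(
        cfg, params, temps, cfg.median_host_init, cfg.median_parasitoid_init, True
    )
    without_traj = run_simulation(
        cfg, params, temps, cfg.median_host_init, cfg.median_parasitoid_init, False
    )
    return peak_reduction(with_traj, without_traj)


def sweep_lifespan(
    cfg: SimulationConfig,
    params: ModelParameters,
    temps: TemperatureSeries,
    grid=None,
) -> pd.DataFrame:
    """Peak pest reduction vs mean adult parasitoid lifespan (2-26 d).

    Lifespan L is mapped to a fixed daily survival P3 = 1 - 1/L
    (geometric-lifetime identity), uncoupled from host density.
    """
    grid = np.arange(2.0, 27.0, 1.0) if grid is None else np.asarray(grid, dtype=float)
    if (grid <= 1.0).any():
        raise ParameterError("lifespans must exceed 1 day")
    rows = []
    for L in grid:
        cfg_L = replace(cfg, adult_survival_constant=1.0 - 1.0 / L)
        rows.append({"lifespan_d": float(L),
                     "peak_reduction_pct": _paired_reduction(cfg_L, params, temps)})
    return pd.DataFrame(rows)


def sweep_colonization(
    cfg: SimulationConfig,
    params: ModelParameters,
    temps: TemperatureSeries,
    grid=None,
) -> pd.DataFrame:
    """Peak pest reduction vs parasitoid colonization delay (2-32 d after
    host establishment)."""
    grid = np.arange(2, 33) if grid is None else np.asarray(grid, dtype=int)
    if (grid > cfg.horizon_days).any():
        raise ValueError("colonization delay exceeds the simulation horizon")
    rows = []
    for delay in grid:
        cfg_d = replace(cfg, parasitoid_delay_days=int(delay))
        rows.append({"colonization_delay_d": int(delay),
                     "peak_reduction_pct": _paired_reduction(cfg_d, params, temps)})
    return pd.DataFrame(rows)


def preference_grid(n_levels: int = 21) -> list[tuple[float, ...]]:
    """Graded host-stage preference vectors, juvenile anchor -> uniform ->
    adult anchor, by piecewise-linear interpolation on the simplex.

    ``n_levels`` must be odd so the uniform vector sits exactly in the
    middle.
    """
    if n_levels < 3 or n_levels % 2 == 0:
        raise ValueError("n_levels must be an odd integer >= 3")
    half = n_levels // 2
    juv = np.asarray(JUVENILE_ANCHOR)
    uni = np.asarray(UNIFORM_PREFERENCE)
    adu = np.asarray(ADULT_ANCHOR)
    grid = [tuple(juv + (uni - juv) * k / half) for k in range(half)]
    grid += [tuple(uni + (adu - uni) * k / half) for k in range(half + 1)]
    return grid


def sweep_preference(
    cfg: SimulationConfig,
    params: ModelParameters,
    temps: TemperatureSeries,
    n_levels: int = 21,
) -> pd.DataFrame:
    """Peak pest reduction across the graded host-stage preference gradient."""
    rows = []
    for level, a in enumerate(preference_grid(n_levels), start=1):
        p = params.with_attack_fractions(a)
        rows.append({
            "level": level,
            "a1": a[0], "a2": a[1], "a3": a[2], "a4": a[3], "a5": a[4],
            "peak_reduction_pct": _paired_reduction(cfg, p, temps),
        })
    return pd.DataFrame(rows)


def sweep_temperature(
    cfg: SimulationConfig,
    params: ModelParameters,
    temps: TemperatureSeries,
    offsets=None,
) -> pd.DataFrame:
    """Peak pest reduction vs a uniform shift of the daily temperature
    series (-3..+3 degC)."""
    offsets = np.arange(-3.0, 3.5, 0.5) if offsets is None else np.asarray(offsets, dtype=float)
    rows = []
    for off in offsets:
        rows.append({"offset_degC": float(off),
                     "peak_reduction_pct": _paired_reduction(cfg, params, temps.with_offset(off))})
    return pd.DataFrame(rows)


def exclusion_experiment(
    cfg: SimulationConfig,
    params: ModelParameters,
    temps: TemperatureSeries,
) -> dict:
    """Effect of removing post-parasitism reproduction (J_i = 0).

    Runs two same-seed paired ensembles and returns the change in mean
    peak pest reduction, (without term) - (with term); removing the
    hosts' compensatory reproduction can only help suppression, so the
    delta is expected to be small and non-negative.
    """
    with_term = run_ensemble(cfg, params, temps)
    without_term = run_ensemble(
        cfg, params.without_post_parasitism_reproduction(), temps
    )
    r_with = float(with_term.peak_reduction.mean())
    r_without = float(without_term.peak_reduction.mean())
    return {
        "mean_reduction_with_term_pct": r_with,
        "mean_reduction_without_term_pct": r_without,
        "delta_pct": r_without - r_with,
    }
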