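"""Daily simulation loop, Monte-Carlo field-season ensemble, and
parasitism/suppression summary statistics.

A field season is simulated for 90 days from host colonization (June 22 by
default); the parasitoid arrives as mummies 20 days later.  Initial
densities are drawn uniformly from the ranges observed at four Minnesota
field sites (0.3-1.82 aphids and 0.15-4.08 mummies per plant), with the
host starting entirely in the first stadium and the parasitoid entirely in
the mummy stage (both populations juvenile-biased, as in newly colonized
fields).  Each replicate is paired: a with-parasitoid and a host-only run
share the host initial density and the temperature series, so "peak pest
reduction" is computed within replicates.

Three measures of parasitism are tracked daily:

* parasitism rate   sum_i (1 - g_i) n_i / N   (fraction attacked per day)
* percent parasitism  100 * p1 / N            (standing parasitized share)
* mummy fraction     p2 / (N + p2)            (the field-countable measure)

The ensemble engine advances all replicates simultaneously on stacked
state arrays; it is verified against the single-trajectory path in the
test suite.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import core, thermal
from .params import ModelParameters
from .weather import TemperatureSeries

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "EnsembleResult",
    "parasitism_measures",
    "peak_reduction",
    "run_simulation",
    "run_ensemble",
]

HOST_INIT_RANGE = (0.3, 1.82)
PARASITOID_INIT_RANGE = (0.15, 4.08)
DEFAULT_START = dt.date(2017, 6, 22)


@dataclass(frozen=True)
class SimulationConfig:
    """Field-season protocol settings.

    ``adult_survival_constant`` fixes the daily adult parasitoid survival
    probability (disabling host-density dependence); ``decreasing_r_rate``
    switches on the decreasing-r variant in which the host projection
    matrix is damped by lambda_A**(-a*t) as plant quality declines.
    """

    start_date: dt.date = DEFAULT_START
    parasitoid_delay_days: int = 20
    horizon_days: int = 90
    n_reps: int = 10000
    host_init_range: tuple[float, float] = HOST_INIT_RANGE
    parasitoid_init_range: tuple[float, float] = PARASITOID_INIT_RANGE
    escape_mode: str = "literal"
    survival_mode: str = "scaled_max"
    adult_survival_constant: float | None = None
    decreasing_r_rate: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("host_init_range", "parasitoid_init_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be ordered and non-negative; got ({lo}, {hi})")
        if self.horizon_days < self.parasitoid_delay_days:
            raise ValueError(
                f"horizon_days ({self.horizon_days}) must cover "
                f"parasitoid_delay_days ({self.parasitoid_delay_days})"
            )

    @property
    def median_host_init(self) -> float:
        lo, hi = self.host_init_range
        return 0.5 * (lo + hi)

    @property
    def median_parasitoid_init(self) -> float:
        lo, hi = self.parasitoid_init_range
        return 0.5 * (lo + hi)


def parasitism_measures(
    n: np.ndarray, p: np.ndarray, g: np.ndarray
) -> tuple[float, float, float]:
    """(parasitism rate 1/d, percent parasitism %, mummy fraction).

    All three are 0 when their denominator is 0.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    N = n.sum() + p[0]
    rate = float(((1.0 - np.asarray(g)) * n).sum() / N) if N > 0 else 0.0
    percent = float(100.0 * p[0] / N) if N > 0 else 0.0
    mummy = float(p[1] / (N + p[1])) if N + p[1] > 0 else 0.0
    return rate, percent, mummy


@dataclass
class Trajectory:
    """Daily record of one simulated season (day 0..horizon)."""

    config: SimulationConfig
    n: np.ndarray          # (days+1, 5)
    p: np.ndarray          # (days+1, 3)
    g: np.ndarray          # (days+1, 5) escape probabilities at each day's state
    temperature: np.ndarray  # (days+1,) temperature driving each day's step
    N: np.ndarray          # (days+1,) total living hosts
    rate: np.ndarray       # (days+1,)
    percent: np.ndarray    # (days+1,)
    mummy: np.ndarray      # (days+1,)

    @property
    def peak(self) -> float:
        return float(self.N.max())

    @property
    def peak_day(self) -> int:
        return int(self.N.argmax())

    def to_frame(self) -> pd.DataFrame:
        days = np.arange(self.N.size)
        df = pd.DataFrame({"day": days, "temperature": self.temperature, "N": self.N})
        for i in range(5):
            df[f"n{i + 1}"] = self.n[:, i]
        for i, name in enumerate(("p1", "p2", "p3")):
            df[name] = self.p[:, i]
        df["parasitism_rate"] = self.rate
        df["percent_parasitism"] = self.percent
        df["mummy_fraction"] = self.mummy
        return df


def _daily_scaling(T: float, params: ModelParameters):
    """Temperature-scaling matrices for one day."""
    host_c = thermal.scaling_factor(T, params.host.thermal)
    c1 = thermal.scaling_factor(T, params.parasitoid.thermal_egg_to_mummy)
    c2 = thermal.scaling_factor(T, params.parasitoid.thermal_mummy_to_adult)
    C_sba = thermal.build_host_scaling_matrix(host_c, params.host)
    C_ac = thermal.build_parasitoid_scaling_matrix(c1, c2, c2, params.parasitoid)
    return C_sba, C_ac


def run_simulation(
    cfg: SimulationConfig,
    params: ModelParameters,
    temps: TemperatureSeries,
    host_init: float,
    para_init: float,
    include_parasitoid: bool = True,
) -> Trajectory:
    """Run one season and record the daily state.

    Day 0 starts with ``host_init`` first-stadium aphids per plant and no
    parasitoids; on day ``parasitoid_delay_days`` the mummy stage gains
    ``para_init`` (if ``include_parasitoid``).  Each day all matrices are
    built from the same time-t state before either population is advanced
    (synchronous update).
    """
    if len(temps) < cfg.horizon_days:
        raise ValueError(
            f"temperature series covers {len(temps)} days; need {cfg.horizon_days}"
        )
    hp, pp = params.host, params.parasitoid
    A = core.build_host_matrix(hp)
    lam_A = None
    if cfg.decreasing_r_rate is not None:
        lam_A = float(np.max(np.abs(np.linalg.eigvals(A))))

    days = cfg.horizon_days
    n_rec = np.zeros((days + 1, 5))
    p_rec = np.zeros((days + 1, 3))
    g_rec = np.zeros((days + 1, 5))
    T_rec = np.zeros(days + 1)
    state = core.PopulationState(np.array([host_init, 0, 0, 0, 0.0]), np.zeros(3))

    for t in range(days + 1):
        if include_parasitoid and t == cfg.parasitoid_delay_days:
            state.p[1] += para_init
        g = core.escape_probabilities(state, pp, cfg.escape_mode)
        n_rec[t] = state.n
        p_rec[t] = state.p
        g_rec[t] = g
        T_rec[t] = temps.values[min(t, days - 1)]
        if t == days:
            break
        T = temps.values[t]
        C_sba, C_ac = _daily_scaling(T, params)
        H = core.build_escape_matrix(g)
        W = core.build_parasitoid_matrix(
            state, pp, g, cfg.survival_mode, cfg.adult_survival_constant
        )
        recruits = core.post_parasitism_recruits(state, hp)
        damping = 1.0
        if cfg.decreasing_r_rate is not None:
            damping = lam_A ** (-cfg.decreasing_r_rate * t)
        n_next = core.host_step(state, A, H, C_sba, hp, recruits, damping)
        p_next = core.parasitoid_step(state, W, C_ac, hp)
        state = core.PopulationState(n_next, p_next)

    N = n_rec.sum(axis=1) + p_rec[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(N > 0, ((1.0 - g_rec) * n_rec).sum(axis=1) / np.where(N > 0, N, 1), 0.0)
        percent = np.where(N > 0, 100.0 * p_rec[:, 0] / np.where(N > 0, N, 1), 0.0)
        denom = N + p_rec[:, 1]
        mummy = np.where(denom > 0, p_rec[:, 1] / np.where(denom > 0, denom, 1), 0.0)
    return Trajectory(cfg, n_rec, p_rec, g_rec, T_rec, N, rate, percent, mummy)


def peak_reduction(traj_with: Trajectory, traj_without: Trajectory) -> float:
    """Percent difference in peak total host density, with vs without the
    parasitoid: 100*(peak_without - peak_with)/peak_without."""
    peak_wo = traj_without.peak
    if peak_wo <= 0:
        raise ValueError("peak host density without the parasitoid is zero")
    return float(100.0 * (peak_wo - traj_with.peak) / peak_wo)


# ---------------------------------------------------------------------------
# vectorized ensemble engine


def _ensemble_step(
    n: np.ndarray,
    p: np.ndarray,
    params: ModelParameters,
    T: float,
    cfg: SimulationConfig,
    damping: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance stacked states (R,5)/(R,3) one day; returns (n', p', g)."""
    hp, pp = params.host, params.parasitoid
    R = n.shape[0]
    N = n.sum(axis=1) + p[:, 0]                      # (R,)
    sum_n = n.sum(axis=1)
    a = pp.a_arr[None, :]                            # (1,5)
    p3f = (p[:, 2] * pp.prop_female)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        avail = np.where(N > 0, sum_n / np.where(N > 0, N, 1), 0.0)[:, None]
        expo = -a * pp.alpha * p3f / (1.0 + a * pp.alpha * pp.handling_time * N[:, None])
        if cfg.escape_mode == "scaled_exponent":
            g = np.exp(expo * avail)
        else:
            g = np.exp(expo) * avail
    g = np.where((N > 0)[:, None], g, 1.0)

    host_c = thermal.scaling_factor(T, hp.thermal)
    c1 = thermal.scaling_factor(T, pp.thermal_egg_to_mummy)
    c2 = thermal.scaling_factor(T, pp.thermal_mummy_to_adult)
    cP_host = np.array([thermal.survival_scaling(hp.P[i], host_c) for i in range(4)])
    cPp1 = thermal.survival_scaling(pp.P[0], c1)
    cPp2 = thermal.survival_scaling(pp.P[1], c2)

    phi = (hp.K - N) / hp.K                          # (R,)
    phi_pos = np.maximum(phi, 0.0)
    decline = np.where(phi >= 0.0, phi, 1.0)

    # host update: M = H o A o C_sba, written out entry by entry
    P, G = hp.P_arr, hp.G_arr
    d = damping
    Mn = np.empty_like(n)
    Mn[:, 0] = d * (g[:, 0] * P[0] * cP_host[0] * n[:, 0]
                    + g[:, 4] * hp.F5 * host_c ** 4 * n[:, 4])
    Mn[:, 1] = d * (g[:, 0] * G[0] * host_c * n[:, 0]
                    + g[:, 1] * P[1] * cP_host[1] * n[:, 1])
    Mn[:, 2] = d * (g[:, 0] * hp.G_skip13 * host_c * n[:, 0]
                    + g[:, 1] * G[1] * host_c * n[:, 1]
                    + g[:, 2] * P[2] * cP_host[2] * n[:, 2])
    Mn[:, 3] = d * (g[:, 2] * G[2] * host_c * n[:, 2]
                    + g[:, 3] * P[3] * cP_host[3] * n[:, 3])
    Mn[:, 4] = d * (g[:, 3] * G[3] * host_c * n[:, 3]
                    + g[:, 4] * P[4] * host_c * n[:, 4])
    with np.errstate(invalid="ignore", divide="ignore"):
        recruits = np.where(
            N > 0, p[:, 0] * (hp.J_arr[None, :] * n).sum(axis=1) / np.where(N > 0, N, 1), 0.0
        )
    d = Mn - n
    # above K the logistic factor reverses growth but must not amplify
    # decline into growth (see core.host_step)
    n_next = n + np.where(
        (phi >= 0.0)[:, None],
        phi[:, None] * d,
        phi[:, None] * np.maximum(d, 0.0) + np.minimum(d, 0.0),
    )
    n_next[:, 0] += recruits
    n_next = np.maximum(n_next, 0.0)

    # parasitoid update
    if cfg.adult_survival_constant is not None:
        P3 = np.full(R, cfg.adult_survival_constant)
    else:
        denom = 1.0 + pp.theta2 * np.exp(pp.theta3 * N)
        if cfg.survival_mode == "scaled_max":
            P3 = pp.S_adult_max / denom
        else:
            lifespan = pp.theta1 / denom
            P3 = np.clip(1.0 - 1.0 / lifespan, 0.0, 1.0)
    attacked = ((1.0 - g) * n).sum(axis=1)           # F3 * p3
    V11 = pp.P[0] * cPp1
    V21 = pp.G[0] * c1
    V22 = pp.P[1] * cPp2
    V32 = pp.G[1] * c2
    V33 = P3 * c2
    eggs = attacked * c2 ** 4                        # V13 * p3 (F3 guarded via attacked)
    eggs = np.where(p[:, 2] > 0, eggs, 0.0)
    p_next = np.empty_like(p)
    p_next[:, 0] = p[:, 0] + decline * (V11 - 1.0) * p[:, 0] + phi_pos * eggs
    p_next[:, 1] = phi_pos * V21 * p[:, 0] + V22 * p[:, 1]
    p_next[:, 2] = V32 * p[:, 1] + V33 * p[:, 2]
    p_next = np.maximum(p_next, 0.0)
    return n_next, p_next, g


@dataclass
class EnsembleResult:
    """Per-replicate peaks and parasitism summaries of a paired ensemble."""

    config: SimulationConfig
    host_init: np.ndarray
    para_init: np.ndarray
    peak_with: np.ndarray
    peak_day_with: np.ndarray
    peak_without: np.ndarray
    peak_day_without: np.ndarray
    peak_reduction: np.ndarray
    rate_at_peak: np.ndarray
    percent_at_peak: np.ndarray
    mummy_at_peak: np.ndarray
    daily: pd.DataFrame    # quantile bands + median measures per day

    @property
    def frac_below_ET(self) -> float:
        return float(np.mean(self.peak_with < self.config_ET)) if self.peak_with.size else float("nan")

    @property
    def frac_below_EIL(self) -> float:
        return float(np.mean(self.peak_with <= self.config_EIL)) if self.peak_with.size else float("nan")

    # thresholds snapshotted at run time (the host params used)
    config_ET: float = 250.0
    config_EIL: float = 674.0

    def summary(self) -> dict:
        def _mean(x):
            return float(x.mean()) if x.size else float("nan")

        def _sd(x):
            return float(x.std(ddof=1)) if x.size > 1 else float("nan")

        return {
            "n_reps": int(self.peak_with.size),
            "mean_peak_reduction_pct": _mean(self.peak_reduction),
            "sd_peak_reduction_pct": _sd(self.peak_reduction),
            "frac_below_ET": self.frac_below_ET,
            "frac_below_EIL": self.frac_below_EIL,
            "mean_rate_at_peak": _mean(self.rate_at_peak),
            "sd_rate_at_peak": _sd(self.rate_at_peak),
            "mean_percent_parasitism_at_peak": _mean(self.percent_at_peak),
            "sd_percent_parasitism_at_peak": _sd(self.percent_at_peak),
            "mean_mummy_fraction_at_peak": _mean(self.mummy_at_peak),
            "sd_mummy_fraction_at_peak": _sd(self.mummy_at_peak),
            "mean_peak_day": _mean(self.peak_day_with),
            "median_peak_without": float(np.median(self.peak_without)) if self.peak_without.size else float("nan"),
        }

    def to_replicate_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(self.peak_with.size),
            "host_init": self.host_init,
            "para_init": self.para_init,
            "peak_with": self.peak_with,
            "peak_day_with": self.peak_day_with,
            "peak_without": self.peak_without,
            "peak_day_without": self.peak_day_without,
            "peak_reduction_pct": self.peak_reduction,
            "rate_at_peak": self.rate_at_peak,
            "percent_parasitism_at_peak": self.percent_at_peak,
            "mummy_fraction_at_peak": self.mummy_at_peak,
        })


def run_ensemble(
    cfg: SimulationConfig,
    params: ModelParameters,
    temps: TemperatureSeries,
) -> EnsembleResult:
    """Run the paired Monte-Carlo field-season ensemble.

    Initial densities are drawn from seeded uniform streams; each
    replicate's host-only partner shares its host initial density and the
    temperature series.  All replicates are advanced simultaneously.
    """
    if len(temps) < cfg.horizon_days:
        raise ValueError(
            f"temperature series covers {len(temps)} days; need {cfg.horizon_days}"
        )
    hp = params.host
    rng = np.random.default_rng(cfg.seed)
    R = cfg.n_reps
    host_init = rng.uniform(*cfg.host_init_range, size=R)
    para_init = rng.uniform(*cfg.parasitoid_init_range, size=R)

    days = cfg.horizon_days
    n_w = np.zeros((R, 5)); n_w[:, 0] = host_init
    p_w = np.zeros((R, 3))
    n_wo = n_w.copy()
    p_wo = np.zeros((R, 3))

    N_w = np.zeros((days + 1, R))
    N_wo = np.zeros((days + 1, R))
    rate = np.zeros((days + 1, R))
    percent = np.zeros((days + 1, R))
    mummy = np.zeros((days + 1, R))
    ptot = np.zeros((days + 1, R))

    lam_A = None
    if cfg.decreasing_r_rate is not None:
        lam_A = float(np.max(np.abs(np.linalg.eigvals(core.build_host_matrix(hp)))))

    for t in range(days + 1):
        if t == cfg.parasitoid_delay_days:
            p_w[:, 1] += para_init
        N_t = n_w.sum(axis=1) + p_w[:, 0]
        N_w[t] = N_t
        N_wo[t] = n_wo.sum(axis=1) + p_wo[:, 0]
        ptot[t] = p_w.sum(axis=1)
        # record measures from the current state (g recomputed cheaply)
        a = params.parasitoid.a_arr[None, :]
        p3f = (p_w[:, 2] * params.parasitoid.prop_female)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            avail = np.where(N_t > 0, n_w.sum(axis=1) / np.where(N_t > 0, N_t, 1), 0.0)
            expo = (-a * params.parasitoid.alpha * p3f
                    / (1.0 + a * params.parasitoid.alpha
                       * params.parasitoid.handling_time * N_t[:, None]))
            if cfg.escape_mode == "scaled_exponent":
                g_t = np.exp(expo * avail[:, None])
            else:
                g_t = np.exp(expo) * avail[:, None]
            g_t = np.where((N_t > 0)[:, None], g_t, 1.0)
            rate[t] = np.where(
                N_t > 0, ((1.0 - g_t) * n_w).sum(axis=1) / np.where(N_t > 0, N_t, 1), 0.0
            )
            percent[t] = np.where(N_t > 0, 100.0 * p_w[:, 0] / np.where(N_t > 0, N_t, 1), 0.0)
            dn = N_t + p_w[:, 1]
            mummy[t] = np.where(dn > 0, p_w[:, 1] / np.where(dn > 0, dn, 1), 0.0)
        if t == days:
            break
        T = float(temps.values[t])
        damping = 1.0
        if cfg.decreasing_r_rate is not None:
            damping = lam_A ** (-cfg.decreasing_r_rate * t)
        n_w, p_w, _ = _ensemble_step(n_w, p_w, params, T, cfg, damping)
        n_wo, p_wo, _ = _ensemble_step(n_wo, p_wo, params, T, cfg, damping)

    peak_day_w = N_w.argmax(axis=0)
    peak_w = N_w.max(axis=0)
    peak_day_wo = N_wo.argmax(axis=0)
    peak_wo = N_wo.max(axis=0)
    reduction = 100.0 * (peak_wo - peak_w) / peak_wo
    cols = np.arange(R)
    daily = pd.DataFrame({
        "day": np.arange(days + 1),
        "N_q25": np.percentile(N_w, 25, axis=1),
        "N_median": np.median(N_w, axis=1),
        "N_q75": np.percentile(N_w, 75, axis=1),
        "N_without_median": np.median(N_wo, axis=1),
        "parasitoid_total_median": np.median(ptot, axis=1),
        "rate_median": np.median(rate, axis=1),
        "percent_parasitism_median": np.median(percent, axis=1),
        "mummy_fraction_median": np.median(mummy, axis=1),
    })
    return EnsembleResult(
        config=cfg,
        host_init=host_init,
        para_init=para_init,
        peak_with=peak_w,
        peak_day_with=peak_day_w,
        peak_without=peak_wo,
        peak_day_without=peak_day_wo,
        peak_reduction=reduction,
        rate_at_peak=rate[peak_day_w, cols],
        percent_at_peak=percent[peak_day_w, cols],
        mummy_at_peak=mummy[peak_day_w, cols],
        daily=daily,
        config_ET=hp.ET,
        config_EIL=hp.EIL,
    )
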