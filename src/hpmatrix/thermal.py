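"""Temperature scaling of the projection matrices.

Laboratory life-table rates were measured at 25 degC.  To run the model on
a field temperature series, each day's matrix entries are rescaled by the
ratio of finite growth rates c = lambda(T)/lambda(25) with lambda = exp(r),
where r(T) comes from a modified Logan curve for the host and Briere-1
curves for the two parasitoid developmental transitions.  Diagonal
(resampling) entries use the compensating factor cP_i = (1 - (1 - P_i)c)/P_i
so that column mass is conserved (cP_i*P_i + c*G_i = P_i + G_i); fertility
entries scale as c**4, the best matrix approximation of the exponential
response of reproduction to temperature.  The lambda-ratio approximation is
trusted on 5-30 degC only, so temperatures are clamped to that window
before computing scaling factors.
"""

from __future__ import annotations

import numpy as np

from .params import (
    HostParams,
    HostThermalCurve,
    ParameterError,
    ParasitoidParams,
    ParasitoidThermalCurve,
)

__all__ = [
    "T_REF",
    "CLAMP_WINDOW",
    "host_growth_rate",
    "parasitoid_growth_rate",
    "scaling_factor",
    "survival_scaling",
    "build_host_scaling_matrix",
    "build_parasitoid_scaling_matrix",
]

T_REF = 25.0
CLAMP_WINDOW = (5.0, 30.0)


def host_growth_rate(T, curve: HostThermalCurve):
    """Host intrinsic growth rate r(T) (1/d), modified Logan form.

    r(T) = exp(rho*T) - exp(rho*T_max - (T_max - T)/delta), floored at 0.
    Zero at and above the upper development threshold T_max.
    """
    T = np.asarray(T, dtype=float)
    r = np.exp(curve.rho * T) - np.exp(
        curve.rho * curve.T_max - (curve.T_max - T) / curve.delta
    )
    return np.maximum(r, 0.0)[()]


def parasitoid_growth_rate(T, curve: ParasitoidThermalCurve):
    """Parasitoid developmental rate r(T) (1/d), Briere-1 form.

    r(T) = a * T * (T - T0) * sqrt(T_max - T) inside [T0, T_max], else 0.
    """
    T = np.asarray(T, dtype=float)
    inside = (T >= curve.T0) & (T <= curve.T_max)
    radicand = np.clip(curve.T_max - T, 0.0, None)
    r = np.where(inside, curve.a * T * (T - curve.T0) * np.sqrt(radicand), 0.0)
    return r[()]


def scaling_factor(
    T: float,
    curve: HostThermalCurve | ParasitoidThermalCurve,
    T_ref: float = T_REF,
) -> float:
    """Dimensionless scaling factor c = lambda(T)/lambda(T_ref) = exp(r(T) - r(T_ref)).

    T is clamped to the 5-30 degC validity window of the matrix
    approximation before evaluation; c is 1 at the reference temperature
    and positive everywhere.
    """
    T = float(np.clip(T, *CLAMP_WINDOW))
    if isinstance(curve, HostThermalCurve):
        rate = host_growth_rate
    else:
        rate = parasitoid_growth_rate
    return float(np.exp(rate(T, curve) - rate(T_ref, curve)))


def survival_scaling(P_i: float, c_i: float) -> float:
    """Temperature-compensated resampling factor cP_i = (1 - (1 - P_i)*c_i)/P_i.

    Chosen so that cP_i*P_i + c_i*G_i = P_i + G_i whenever P_i + G_i = 1:
    warming speeds transitions (c*G > G) at the expense of resampling the
    same stage.  The result is clamped to [0, 1/P_i] so the scaled
    survival probability stays in [0, 1].
    """
    if P_i <= 0 or P_i > 1:
        raise ParameterError(f"P_i must lie in (0, 1]; got {P_i!r}")
    if c_i <= 0:
        raise ParameterError(f"scaling factor must be positive; got {c_i!r}")
    if c_i == 1.0:
        return 1.0  # exact neutrality at the reference temperature
    cP = (1.0 - (1.0 - P_i) * c_i) / P_i
    return float(np.clip(cP, 0.0, 1.0 / P_i))


def build_host_scaling_matrix(c: float, hp: HostParams) -> np.ndarray:
    """Host temperature-scaling matrix C_sba (5x5, A's sparsity).

    One daily factor c (one thermal curve) serves all host stages:
    juvenile diagonal entries cP_i, transition entries c, adult survival
    entry c, fertility entry c**4.
    """
    C = np.zeros((5, 5))
    for i in range(4):
        C[i, i] = survival_scaling(hp.P[i], c)
    C[4, 4] = c
    C[np.arange(1, 5), np.arange(4)] = c
    C[2, 0] = c
    C[0, 4] = c ** 4
    return C


def build_parasitoid_scaling_matrix(
    c1: float, c2: float, c3: float, pp: ParasitoidParams
) -> np.ndarray:
    """Parasitoid temperature-scaling matrix C_ac (3x3, W's sparsity).

    c1 scales the egg+larva stage (egg-to-mummy curve), c2 the mummy stage
    (mummy-to-adult curve), c3 the adult survival entry; fertility scales
    as c3**4.
    """
    C = np.zeros((3, 3))
    C[0, 0] = survival_scaling(pp.P[0], c1)
    C[1, 0] = c1
    C[1, 1] = survival_scaling(pp.P[1], c2)
    C[2, 1] = c2
    C[2, 2] = c3
    C[0, 2] = c3 ** 4
    return C
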