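"""One-day projection step of the coupled host-parasitoid system.

The host population vector ``n`` (five stages) is projected with a
transition/fertility matrix ``A``, an escape-probability matrix ``H`` and a
temperature-scaling matrix ``C_sba``; the parasitoid vector ``p`` (egg+larva
inside a living host, mummy, adult) with a matrix ``W`` scaled by ``C_ac``.
The two populations are coupled through the escape function ``g`` — a
Nicholson-Bailey-style survivorship term derived from a type II functional
response — and through a shared logistic carrying-capacity factor
``phi = (K - N)/K`` where ``N = sum(n) + p1`` counts every living host,
parasitized or not.

All matrix "products" here are elementwise (Hadamard) over a shared sparsity
pattern: ``H`` and ``C`` rescale individual entries of ``A`` (and ``W``);
a true matrix product would mix structurally unrelated terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import HostParams, ParasitoidParams, ParameterError

__all__ = [
    "PopulationState",
    "build_host_matrix",
    "escape_probabilities",
    "build_escape_matrix",
    "adult_parasitoid_survival",
    "build_parasitoid_matrix",
    "post_parasitism_recruits",
    "host_step",
    "parasitoid_step",
]

#: structural (row, col) indices, 0-based, of the host matrices A, H, C_sba
HOST_SPARSITY = (
    (0, 0), (0, 4),
    (1, 0), (1, 1),
    (2, 0), (2, 1), (2, 2),
    (3, 2), (3, 3),
    (4, 3), (4, 4),
)
#: structural indices of the parasitoid matrices W, C_ac
PARASITOID_SPARSITY = ((0, 0), (0, 2), (1, 0), (1, 1), (2, 1), (2, 2))


@dataclass
class PopulationState:
    """Densities of the host (``n``, 5 stages) and parasitoid (``p``, 3 stages).

    ``p[0]`` counts still-living parasitized hosts (egg/larval parasitoids),
    ``p[1]`` mummies, ``p[2]`` adult wasps.  Densities are continuous,
    per-plant, and non-negative.
    """

    n: np.ndarray = field(default_factory=lambda: np.zeros(5))
    p: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.n.shape != (5,):
            raise ValueError(f"n must be a 5-vector; got shape {self.n.shape}")
        if self.p.shape != (3,):
            raise ValueError(f"p must be a 3-vector; got shape {self.p.shape}")
        if (self.n < 0).any() or (self.p < 0).any():
            raise ValueError("population densities must be non-negative")

    @property
    def N(self) -> float:
        """Total living hosts: unparasitized plus parasitized-but-alive."""
        return float(self.n.sum() + self.p[0])

    @property
    def total_parasitoids(self) -> float:
        return float(self.p.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(self.n.copy(), self.p.copy())


def build_host_matrix(hp: HostParams) -> np.ndarray:
    """Host transition/fertility matrix A (5x5).

    Diagonal: stage survival P1..P5; subdiagonal: transitions G1..G4;
    (3,1): the 1st-to-3rd stadium skip probability; (1,5): adult
    fecundity F5.
    """
    A = np.zeros((5, 5))
    A[np.diag_indices(5)] = hp.P_arr
    A[np.arange(1, 5), np.arange(4)] = hp.G_arr
    A[2, 0] = hp.G_skip13
    A[0, 4] = hp.F5
    return A


def escape_probabilities(
    state: PopulationState,
    pp: ParasitoidParams,
    mode: str = "literal",
) -> np.ndarray:
    """Stage-specific probabilities g_i of escaping parasitism for one day.

    Derived from a type II functional response: the per-female attack
    pressure on stage i is a_i * alpha / (1 + a_i * alpha * T_h * N), and
    only the fraction sum(n)/N of living hosts is still available for
    attack (parasitized hosts cannot be re-parasitized).

    mode="literal" (default): the available-host fraction multiplies the
    exponential outside,
    g_i = exp(-a_i*alpha*p3_female / (1 + a_i*alpha*T_h*N)) * (sum(n)/N).
    mode="scaled_exponent": it scales the exponent instead,
    g_i = exp(-a_i*alpha*p3_female*(sum(n)/N) / (1 + a_i*alpha*T_h*N)),
    so that g = 1 exactly when no adult females are present.

    With no hosts at all (N = 0) every g_i is 1.
    """
    if mode not in ("scaled_exponent", "literal"):
        raise ValueError(f"unknown escape mode {mode!r}")
    N = state.N
    if N == 0.0:
        return np.ones(5)
    a = pp.a_arr
    p3_female = state.p[2] * pp.prop_female
    avail = state.n.sum() / N
    exponent = -a * pp.alpha * p3_female / (1.0 + a * pp.alpha * pp.handling_time * N)
    if mode == "scaled_exponent":
        g = np.exp(exponent * avail)
    else:
        g = np.exp(exponent) * avail
    return g


def build_escape_matrix(g: np.ndarray) -> np.ndarray:
    """Escape matrix H (5x5) sharing A's sparsity.

    Every entry is the escape probability of the *origin* stage: diagonal
    g_i, subdiagonal g_i, skip entry g_1, fertility entry g_5 (an adult
    must escape attack to reproduce).
    """
    g = np.asarray(g, dtype=float)
    if g.shape != (5,):
        raise ValueError(f"g must be a 5-vector; got shape {g.shape}")
    if (g < 0).any() or (g > 1).any():
        raise ValueError(f"escape probabilities must lie in [0, 1]; got {g!r}")
    H = np.zeros((5, 5))
    H[np.diag_indices(5)] = g
    H[np.arange(1, 5), np.arange(4)] = g[:4]
    H[2, 0] = g[0]
    H[0, 4] = g[4]
    return H


def adult_parasitoid_survival(
    N_total: float, pp: ParasitoidParams, mode: str = "scaled_max"
) -> float:
    """Daily adult parasitoid survival as a function of host density.

    Mean adult lifespan follows a Verhulst (logistic) curve
    Lambda(N) = theta1 / (1 + theta2 * exp(theta3 * N)); with theta3 < 0
    lifespan (and hence survival) rises with host density, saturating at
    theta1 days.

    mode="scaled_max" (default): P3(N) = S_adult_max * Lambda(N)/theta1
    = S_adult_max / (1 + theta2*exp(theta3*N)), which saturates at the
    tabulated maximum daily survival.
    mode="inverse_lifespan": P3(N) = 1 - 1/Lambda(N) (geometric-lifetime
    identity), clamped to [0, 1].
    """
    if mode not in ("scaled_max", "inverse_lifespan"):
        raise ValueError(f"unknown adult-survival mode {mode!r}")
    denom = 1.0 + pp.theta2 * np.exp(pp.theta3 * N_total)
    if mode == "scaled_max":
        return float(pp.S_adult_max / denom)
    lifespan = pp.theta1 / denom
    return float(min(max(1.0 - 1.0 / lifespan, 0.0), 1.0))


def build_parasitoid_matrix(
    state: PopulationState,
    pp: ParasitoidParams,
    g: np.ndarray,
    survival_mode: str = "scaled_max",
    adult_survival_override: float | None = None,
) -> np.ndarray:
    """Parasitoid transition/fertility matrix W (3x3).

    Fertility F3 = sum_i (1 - g_i) * n_i / p3 places one egg in every
    attacked host, so W[1,3]*p3 equals the total newly parasitized hosts.
    ``adult_survival_override`` fixes the adult survival probability,
    bypassing host-density dependence (used by the lifespan sensitivity
    sweep).
    """
    W = np.zeros((3, 3))
    W[0, 0] = pp.P[0]
    W[1, 0] = pp.G[0]
    W[1, 1] = pp.P[1]
    W[2, 1] = pp.G[1]
    if adult_survival_override is not None:
        W[2, 2] = adult_survival_override
    else:
        W[2, 2] = adult_parasitoid_survival(state.N, pp, survival_mode)
    p3 = state.p[2]
    W[0, 2] = float(((1.0 - np.asarray(g)) * state.n).sum() / p3) if p3 > 0 else 0.0
    return W


def post_parasitism_recruits(state: PopulationState, hp: HostParams) -> float:
    """First-stadium offspring produced by parasitized-but-living hosts.

    Parasitized hosts are assumed to share the stage structure of the
    unparasitized population, so the recruits are
    sum_i p1 * J_i * n_i / N (zero when N = 0 or p1 = 0).
    """
    N = state.N
    p1 = state.p[0]
    if N == 0.0 or p1 == 0.0:
        return 0.0
    return float((p1 * hp.J_arr * state.n / N).sum())


def host_step(
    state: PopulationState,
    A: np.ndarray,
    H: np.ndarray,
    C_sba: np.ndarray,
    hp: HostParams,
    recruits: float = 0.0,
    damping: float = 1.0,
) -> np.ndarray:
    """Advance the host vector one day.

    n(t+1) = n(t) + phi * (damping * (H o A o C_sba) - I) n(t), with
    phi = (K - N)/K the logistic carrying-capacity factor.  ``recruits``
    (offspring of parasitized hosts) are then added to the first stadium
    and the result clamped at zero.  ``damping`` < 1 implements the
    decreasing-r variant (see :mod:`hpmatrix.experiments`).

    Above the carrying capacity (phi < 0) the increment is not applied
    verbatim: growth components of (M - I)n are still reversed by phi (the
    population declines), but decline components proceed at their
    intrinsic rate instead of being amplified by the negative factor —
    extrapolating the quadratic logistic term there turns mortality into
    growth and makes the explicit one-day update divergent.
    """
    if not (A.shape == H.shape == C_sba.shape == (5, 5)):
        raise ValueError("A, H and C_sba must all be 5x5")
    N = state.N
    phi = (hp.K - N) / hp.K
    M = damping * (H * A * C_sba)
    d = M @ state.n - state.n
    if phi >= 0:
        n_next = state.n + phi * d
    else:
        n_next = state.n + phi * np.maximum(d, 0.0) + np.minimum(d, 0.0)
    n_next[0] += recruits
    return np.maximum(n_next, 0.0)


def parasitoid_step(
    state: PopulationState,
    W: np.ndarray,
    C_ac: np.ndarray,
    hp: HostParams,
) -> np.ndarray:
    """Advance the parasitoid vector one day.

    The update is additively decomposed so that the host carrying capacity
    acts on the egg+larva stage, which lives inside a host and competes
    for the same resource:

        p(t+1) = [p1,0,0] + phi*(V - I)[p1,0,0] + phi*[V13*p3, 0, 0]
                 + V [0,p2,p3],                          V = W o C_ac

    The egg inflow V13*p3 is throttled by phi as well, so that hosts
    entering the parasitized pool match the phi-throttled parasitism
    losses on the host side of the model (otherwise individuals are
    created out of nothing as N approaches K and the coupled system
    diverges).  Mummy and adult dynamics are never throttled.  Above the
    carrying capacity phi is floored at 0 for inflow terms and the
    egg+larva stage dies at its intrinsic rate (the negative logistic
    factor must not turn its mortality into growth).  Entries are clamped
    at zero.
    """
    if not (W.shape == C_ac.shape == (3, 3)):
        raise ValueError("W and C_ac must both be 3x3")
    N = state.N
    phi = (hp.K - N) / hp.K
    phi_pos = max(phi, 0.0)
    decline = phi if phi >= 0 else 1.0
    V = W * C_ac
    p1, p2, p3 = state.p
    p_next = np.array([
        p1 + decline * (V[0, 0] - 1.0) * p1 + phi_pos * V[0, 2] * p3,
        phi_pos * V[1, 0] * p1 + V[1, 1] * p2,
        V[2, 1] * p2 + V[2, 2] * p3,
    ])
    return np.maximum(p_next, 0.0)
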