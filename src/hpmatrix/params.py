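"""Parameter bundles for the coupled host-parasitoid matrix model.

The model couples a 5-stage soybean aphid (*Aphis glycines*) population
(four nymphal stadia plus the apterous adult) to a 3-stage parasitoid
(*Aphelinus certus*) population (egg+larva inside a living host, mummy,
adult) on a daily projection interval.  All parameters are daily rates or
probabilities measured at a 25 degC reference temperature; temperature
scaling is applied separately (see :mod:`hpmatrix.thermal`).

Default values ship with the package (``data/default_params.yaml``) and can
be loaded with :func:`load_parameters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "HostParams",
    "ParasitoidParams",
    "HostThermalCurve",
    "ParasitoidThermalCurve",
    "ModelParameters",
    "load_parameters",
    "save_parameters",
]

_PROB_TOL = 1e-9


class ParameterError(ValueError):
    """Raised when a parameter bundle violates a model constraint."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1]; got {value!r}")


@dataclass(frozen=True)
class HostThermalCurve:
    """Modified Logan growth-rate curve for the host.

    r(T) = exp(rho*T) - exp(rho*T_max - (T_max - T)/delta), floored at 0.

    Parameters
    ----------
    rho : float
        Exponential rate constant (1/degC).
    T_max : float
        Upper development threshold / maximum lethal temperature (degC).
    delta : float
        Range of thermal breakdown (degC).
    """

    rho: float = 0.14
    T_max: float = 34.9
    delta: float = 7.1

    def __post_init__(self) -> None:
        if self.T_max <= 0:
            raise ParameterError(f"T_max must be positive; got {self.T_max!r}")
        if self.delta <= 0:
            raise ParameterError(f"delta must be positive; got {self.delta!r}")


@dataclass(frozen=True)
class ParasitoidThermalCurve:
    """Briere-1 growth-rate curve for a parasitoid developmental transition.

    r(T) = a * T * (T - T0) * sqrt(T_max - T) on [T0, T_max], else 0.

    Parameters
    ----------
    a : float
        Scale constant.
    T0 : float
        Lower development threshold (degC).
    T_max : float
        Upper development threshold (degC).
    stage_label : str
        Which transition the curve describes ("egg_to_mummy" or
        "mummy_to_adult").
    """

    a: float
    T0: float
    T_max: float
    stage_label: str = ""

    def __post_init__(self) -> None:
        if not self.T0 < self.T_max:
            raise ParameterError(
                f"thermal curve {self.stage_label or ''} requires T0 < T_max; "
                f"got T0={self.T0!r}, T_max={self.T_max!r}"
            )


@dataclass(frozen=True)
class HostParams:
    """Host (soybean aphid) life-history parameters.

    ``P`` holds the daily stage-survival (resampling) probabilities
    P1..P5, ``G`` the daily stage-transition probabilities G1..G4.  A
    first stadium may additionally be resampled as a third stadium one day
    later with probability ``G_skip13`` (fast molters skipping a 12-hour
    sampling window), so P1 + G1 + G_skip13 = 1.  ``F5`` is the adult
    per-capita daily fecundity; ``J`` the per-capita daily fecundity of
    parasitized hosts by the stage at which they were parasitized.  ``K``
    is the carrying capacity of the *total* living host population, and
    ``ET``/``EIL`` are the economic threshold and economic injury level
    used to summarize simulated outbreaks.
    """

    P: tuple[float, ...] = (0.500, 0.143, 0.311, 0.205, 0.86)
    G: tuple[float, ...] = (0.484, 0.857, 0.689, 0.795)
    G_skip13: float = 0.016
    F5: float = 2.56
    J: tuple[float, ...] = (0.0, 0.0, 0.563, 1.521, 1.471)
    K: float = 6000.0
    ET: float = 250.0
    EIL: float = 674.0
    thermal: HostThermalCurve = field(default_factory=HostThermalCurve)

    def __post_init__(self) -> None:
        if len(self.P) != 5:
            raise ParameterError(f"host P must have 5 entries; got {len(self.P)}")
        if len(self.G) != 4:
            raise ParameterError(f"host G must have 4 entries; got {len(self.G)}")
        if len(self.J) != 5:
            raise ParameterError(f"host J must have 5 entries; got {len(self.J)}")
        for i, v in enumerate(self.P, start=1):
            _check_prob(f"host P{i}", v)
        for i, v in enumerate(self.G, start=1):
            _check_prob(f"host G{i}", v)
        _check_prob("host G_skip13", self.G_skip13)
        if self.F5 < 0:
            raise ParameterError(f"host F5 must be >= 0; got {self.F5!r}")
        for i, v in enumerate(self.J, start=1):
            if v < 0:
                raise ParameterError(f"host J{i} must be >= 0; got {v!r}")
        if self.K <= 0:
            raise ParameterError(f"host K must be positive; got {self.K!r}")
        for i in range(4):
            total = self.P[i] + self.G[i] + (self.G_skip13 if i == 0 else 0.0)
            if abs(total - 1.0) > _PROB_TOL:
                raise ParameterError(
                    f"host stage {i + 1}: P + G"
                    f"{' + G_skip13' if i == 0 else ''} must equal 1; got {total!r}"
                )

    @property
    def P_arr(self) -> np.ndarray:
        return np.asarray(self.P, dtype=float)

    @property
    def G_arr(self) -> np.ndarray:
        return np.asarray(self.G, dtype=float)

    @property
    def J_arr(self) -> np.ndarray:
        return np.asarray(self.J, dtype=float)


@dataclass(frozen=True)
class ParasitoidParams:
    """Parasitoid (*A. certus*) life-history and attack parameters.

    ``P`` and ``G`` are the daily survival/transition probabilities of the
    egg+larva and mummy stages (P_i + G_i = 1).  Adult survival is
    host-density dependent: mean adult lifespan follows a Verhulst
    (logistic) curve Lambda(N) = theta1 / (1 + theta2*exp(theta3*N)), and
    the daily adult survival probability saturates at ``S_adult_max`` as
    host density grows (theta3 < 0).  ``attack_fractions`` a_i give the
    share of attacks directed at host stage i; ``alpha`` and
    ``handling_time`` are the instantaneous search rate and handling time
    of the type II functional response that defines the escape function.
    ``prop_male`` is the brood sex ratio as the proportion male; only
    females attack.
    """

    P: tuple[float, float] = (0.832, 0.869)
    G: tuple[float, float] = (0.168, 0.131)
    S_adult_max: float = 0.932
    theta1: float = 18.6
    theta2: float = 13.5
    theta3: float = -0.562
    prop_male: float = 0.412
    attack_fractions: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    alpha: float = 0.979
    handling_time: float = 0.045
    thermal_egg_to_mummy: ParasitoidThermalCurve = field(
        default_factory=lambda: ParasitoidThermalCurve(
            1.19e-4, 7.8, 35.7, "egg_to_mummy"
        )
    )
    thermal_mummy_to_adult: ParasitoidThermalCurve = field(
        default_factory=lambda: ParasitoidThermalCurve(
            1.37e-4, 11.6, 36.9, "mummy_to_adult"
        )
    )

    def __post_init__(self) -> None:
        if len(self.P) != 2 or len(self.G) != 2:
            raise ParameterError("parasitoid P and G must each have 2 entries")
        for i in range(2):
            _check_prob(f"parasitoid P{i + 1}", self.P[i])
            _check_prob(f"parasitoid G{i + 1}", self.G[i])
            if abs(self.P[i] + self.G[i] - 1.0) > _PROB_TOL:
                raise ParameterError(
                    f"parasitoid stage {i + 1}: P + G must equal 1; "
                    f"got {self.P[i] + self.G[i]!r}"
                )
        _check_prob("parasitoid S_adult_max", self.S_adult_max)
        _check_prob("parasitoid prop_male", self.prop_male)
        if self.theta1 <= 1:
            raise ParameterError(
                f"theta1 (max mean adult lifespan, days) must exceed 1; "
                f"got {self.theta1!r}"
            )
        if len(self.attack_fractions) != 5:
            raise ParameterError("attack_fractions must have 5 entries")
        a = np.asarray(self.attack_fractions, dtype=float)
        if (a < 0).any():
            raise ParameterError(f"attack_fractions must be >= 0; got {self.attack_fractions!r}")
        if abs(a.sum() - 1.0) > _PROB_TOL:
            raise ParameterError(
                f"attack_fractions must sum to 1; got sum {a.sum()!r}"
            )
        if self.alpha < 0 or self.handling_time < 0:
            raise ParameterError("alpha and handling_time must be >= 0")

    @property
    def a_arr(self) -> np.ndarray:
        return np.asarray(self.attack_fractions, dtype=float)

    @property
    def prop_female(self) -> float:
        return 1.0 - self.prop_male


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter bundle: host plus parasitoid."""

    host: HostParams = field(default_factory=HostParams)
    parasitoid: ParasitoidParams = field(default_factory=ParasitoidParams)

    def with_attack_fractions(self, a: tuple[float, ...]) -> "ModelParameters":
        return replace(self, parasitoid=replace(self.parasitoid, attack_fractions=tuple(a)))

    def without_post_parasitism_reproduction(self) -> "ModelParameters":
        return replace(self, host=replace(self.host, J=(0.0,) * 5))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("P", "G", "J"):
            if key in d["host"]:
                d["host"][key] = list(d["host"][key])
        d["parasitoid"]["P"] = list(d["parasitoid"]["P"])
        d["parasitoid"]["G"] = list(d["parasitoid"]["G"])
        d["parasitoid"]["attack_fractions"] = list(d["parasitoid"]["attack_fractions"])
        return d


def _host_from_dict(d: dict) -> HostParams:
    thermal = d.pop("thermal", None)
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    if thermal is not None:
        kwargs["thermal"] = HostThermalCurve(**thermal)
    return HostParams(**kwargs)


def _parasitoid_from_dict(d: dict) -> ParasitoidParams:
    kwargs = {}
    for k, v in d.items():
        if k in ("thermal_egg_to_mummy", "thermal_mummy_to_adult"):
            label = k.removeprefix("thermal_")
            curve_kwargs = {ck: cv for ck, cv in v.items() if ck != "stage_label"}
            kwargs[k] = ParasitoidThermalCurve(stage_label=label, **curve_kwargs)
        elif isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return ParasitoidParams(**kwargs)


def load_parameters(source: str | Path = "default") -> ModelParameters:
    """Load a :class:`ModelParameters` bundle from a YAML file.

    ``source="default"`` loads the packaged defaults (the fully
    parameterized soybean aphid x *A. certus* system).  The file has two
    top-level sections, ``host`` and ``parasitoid``; every key mirrors a
    dataclass field.  Violated constraints raise :class:`ParameterError`
    naming the offending field.
    """
    if source == "default":
        text = (
            resources.files("hpmatrix") / "data" / "default_params.yaml"
        ).read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "host" not in raw or "parasitoid" not in raw:
        raise ParameterError(
            "parameter file must contain 'host' and 'parasitoid' sections"
        )
    try:
        host = _host_from_dict(dict(raw["host"]))
        para = _parasitoid_from_dict(dict(raw["parasitoid"]))
    except TypeError as exc:  # unknown key
        raise ParameterError(f"unrecognized parameter key: {exc}") from exc
    return ModelParameters(host=host, parasitoid=para)


def save_parameters(params: ModelParameters, path: str | Path) -> Path:
    """Write a parameter bundle to YAML; round-trips with :func:`load_parameters`."""
    path = Path(path)
    path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
    return path
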