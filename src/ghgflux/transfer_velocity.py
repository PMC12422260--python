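"""Gas transfer velocity: u10 extrapolation, k600 registry, Schmidt scaling.

The transfer velocity for gas i is obtained from a wind-based k600
parameterization and Schmidt-number scaling,

    k_i = k600 * (Sc_i / 600)^n ,

with n = -2/3 for a smooth surface and -1/2 for a turbulent one.  The
reservoir policy switches on wind: n = -2/3 for u10 < 3.7 m s^-1 and
-1/2 at or above (strict "<" at the boundary); rivers and estuaries use
n = -1/2 throughout.

k600 parameterizations live in a plain-text registry
(``data/k600_registry.csv``) as documented reconstructions of the
published lake and estuary wind relations (Cole & Caraco 1998; Crusius &
Wanninkhof 2003; Raymond & Cole 2001; Borges et al. 2004), each
config-overridable.  The per-waterbody selection policy mirrors the study
design: lake parameterizations averaged for the reservoir, estuary
parameterizations averaged for the estuary, and the Crusius & Wanninkhof
(2003) relation alone for the river, where it provides the highest
transfer velocity of the lake set and hence a conservative upper limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, DomainError, RegistryLookupError

__all__ = [
    "WindRecord",
    "K600Param",
    "ScalingRule",
    "EnsembleK",
    "extrapolate_u10",
    "k600",
    "scale_to_gas",
    "ensemble_k",
    "load_registry",
    "params_for_waterbody",
    "DEFAULT_RULES",
    "CD10",
    "VON_KARMAN",
    "SMOOTH_TURBULENT_WIND_THRESHOLD",
]

#: Drag coefficient at 10 m height used in the log-profile extrapolation.
CD10 = 0.0013
#: Von Karman constant.
VON_KARMAN = 0.41
#: u10 (m s^-1) below which a lake surface is treated as smooth (n = -2/3).
SMOOTH_TURBULENT_WIND_THRESHOLD = 3.7


@dataclass(frozen=True)
class WindRecord:
    """A wind-speed observation at a known measurement height."""

    speed: float  # m s^-1
    height: float = 10.0  # m
    timestamp: datetime | None = None

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise DomainError(f"speed={self.speed!r} must be >= 0")
        if self.height <= 0:
            raise DomainError(f"height={self.height!r} must be > 0")


def extrapolate_u10(w: WindRecord) -> float:
    """Extrapolate a wind speed to the 10 m reference height.

        u10 = u_z [1 + (Cd10^1/2 / kappa) ln(10/z)]

    Identity at z = 10 m.  Heights above 10 m make the bracket < 1, which
    is physically sensible (wind decreases toward the surface) and allowed.
    """
    bracket = 1.0 + (math.sqrt(CD10) / VON_KARMAN) * math.log(10.0 / w.height)
    return w.speed * bracket


@dataclass(frozen=True)
class K600Param:
    """One named k600(u10) parameterization with applicability metadata.

    ``form``/``a``/``b``/``c`` encode the wind relation:

    - ``power``:       k600 = a + b * u10**c
    - ``exponential``: k600 = a * exp(b * u10)
    - ``linear``:      k600 = a + b * u10
    """

    code: str
    system_class: str  # "lake" | "estuary" | "river"
    form: str
    a: float
    b: float
    c: float = 0.0
    citation: str = ""

    def k600_of_u10(self, u10: float) -> float:
        if u10 < 0:
            raise DomainError(f"u10={u10!r} must be >= 0")
        if self.form == "power":
            return self.a + self.b * u10**self.c
        if self.form == "exponential":
            return self.a * math.exp(self.b * u10)
        if self.form == "linear":
            return self.a + self.b * u10
        raise ConfigurationError(f"unknown k600 form {self.form!r} for {self.code}")


def _default_registry_path() -> Path:
    return Path(str(resources.files("ghgflux.data").joinpath("k600_registry.csv")))


def load_registry(path: str | Path | None = None) -> dict[str, K600Param]:
    """Load the k600 registry (code -> parameterization)."""
    df = pd.read_csv(path if path is not None else _default_registry_path())
    registry: dict[str, K600Param] = {}
    for row in df.itertuples(index=False):
        registry[row.code] = K600Param(
            code=row.code,
            system_class=row.system_class,
            form=row.form,
            a=float(row.a),
            b=float(row.b),
            c=0.0 if pd.isna(row.c) else float(row.c),
            citation=row.citation,
        )
    return registry


_DEFAULT_REGISTRY = load_registry()

#: Parameterization code used exclusively for the river reach.
RIVER_CODE = "CW03"


def k600(param_or_code: K600Param | str, u10: float,
         registry: dict[str, K600Param] | None = None) -> float:
    """Evaluate a registered parameterization at u10 (cm h^-1)."""
    if isinstance(param_or_code, str):
        reg = registry if registry is not None else _DEFAULT_REGISTRY
        try:
            param = reg[param_or_code]
        except KeyError:
            raise RegistryLookupError(
                f"unknown k600 code {param_or_code!r}; registered: "
                f"{sorted(reg)}"
            ) from None
    else:
        param = param_or_code
    return param.k600_of_u10(u10)


@dataclass(frozen=True)
class ScalingRule:
    """Schmidt-exponent policy for one waterbody class.

    ``smooth_below``: u10 threshold under which n = -2/3 applies; ``None``
    means the surface is always treated as turbulent (n = -1/2).
    """

    waterbody_class: str
    smooth_below: float | None = None

    def exponent(self, u10: float) -> float:
        if self.smooth_below is not None and u10 < self.smooth_below:
            return -2.0 / 3.0
        return -0.5


DEFAULT_RULES: dict[str, ScalingRule] = {
    "reservoir": ScalingRule("reservoir", smooth_below=SMOOTH_TURBULENT_WIND_THRESHOLD),
    "river": ScalingRule("river"),
    "estuary": ScalingRule("estuary"),
}


def scale_to_gas(k600_value: float, sc: float, rule: ScalingRule, u10: float) -> float:
    """Scale a k600 to gas i: k_i = k600 (Sc_i/600)^n; identity at Sc = 600."""
    if sc <= 0:
        raise DomainError(f"Schmidt number sc={sc!r} must be > 0")
    return k600_value * (sc / 600.0) ** rule.exponent(u10)


@dataclass(frozen=True)
class EnsembleK:
    """Ensemble k_i with full member provenance."""

    mean: float  # cm h^-1
    members: dict[str, float] = field(default_factory=dict)
    n_exponent: float = -0.5


def ensemble_k(
    params: list[K600Param], u10: float, sc: float, rule: ScalingRule
) -> EnsembleK:
    """Arithmetic-mean k_i over a parameterization ensemble.

    Retains every member value in the result so downstream provenance can
    record which relations contributed.
    """
    if not params:
        raise ConfigurationError("ensemble_k requires a non-empty parameterization list")
    n = rule.exponent(u10)
    members = {p.code: scale_to_gas(p.k600_of_u10(u10), sc, rule, u10) for p in params}
    return EnsembleK(
        mean=sum(members.values()) / len(members), members=members, n_exponent=n
    )


def params_for_waterbody(
    waterbody: str, registry: dict[str, K600Param] | None = None
) -> list[K600Param]:
    """Default per-waterbody parameterization selection ("auto" policy).

    reservoir -> all lake relations (ensemble-averaged); estuary -> all
    estuary relations; river -> CW03 only.
    """
    reg = registry if registry is not None else _DEFAULT_REGISTRY
    if waterbody == "reservoir":
        return [p for p in reg.values() if p.system_class == "lake"]
    if waterbody == "estuary":
        return [p for p in reg.values() if p.system_class == "estuary"]
    if waterbody == "river":
        try:
            return [reg[RIVER_CODE]]
        except KeyError:
            raise RegistryLookupError(
                f"river policy requires {RIVER_CODE!r} in the registry"
            ) from None
    raise ConfigurationError(f"unknown waterbody {waterbody!r}")
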