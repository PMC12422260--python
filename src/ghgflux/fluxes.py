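"""Diffusive air-water fluxes, ebullition fluxes, and campaign aggregation.

Diffusive flux follows the bulk formulation

    F = k_i * K_i * (pGas_water - pGas_atm)

with k_i in cm h^-1, K_i in mol L^-1 atm^-1 and partial pressures in uatm;
a single collapsed factor of 0.24 (owned by :mod:`ghgflux.units`) carries
the result into mmol m^-2 d^-1.  Positive flux is emission to the
atmosphere; influx (undersaturation) is reported as negative, never
clipped.

Ebullition flux from inverted funnel chambers is the collected gas mass
normalized by funnel area and deployment interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AggregationError, DomainError
from .gas_physics import GasSpecies
from .units import DIFFUSIVE_FLUX_FACTOR, MMOL_PER_MOL

#: Default atmospheric partial pressures (uatm), configurable per run.
DEFAULT_ATM_PARTIAL_PRESSURE = {"CO2": 410.0, "CH4": 1.9}
#: Samples at or above this depth (m) count as "surface" for flux purposes.
DEFAULT_SURFACE_DEPTH_M = 1.0

__all__ = [
    "DEFAULT_ATM_PARTIAL_PRESSURE",
    "DEFAULT_SURFACE_DEPTH_M",
    "FluxEstimate",
    "EbullitionRecord",
    "EbullitionFlux",
    "CampaignSummary",
    "diffusive_flux",
    "ebullition_flux",
    "aggregate_campaign",
]


def diffusive_flux(
    k_i: float, solubility_k: float, p_water: float, p_atm: float
) -> float:
    """Diffusive flux in mmol m^-2 d^-1.

    Parameters are the gas transfer velocity (cm h^-1), the solubility
    constant (mol L^-1 atm^-1) and the water/atmosphere partial pressures
    (uatm).  Linear separately in k_i and in the pressure difference;
    exactly zero at equilibrium.
    """
    if k_i < 0:
        raise DomainError(f"k_i={k_i!r} must be >= 0")
    if solubility_k <= 0:
        raise DomainError(f"solubility_k={solubility_k!r} must be > 0")
    return DIFFUSIVE_FLUX_FACTOR * k_i * solubility_k * (p_water - p_atm)


@dataclass(frozen=True)
class FluxEstimate:
    """Per-station, per-gas areal flux with provenance.

    Sign convention: positive = emission to the atmosphere, so
    sign(flux) = sign(p_water - p_atm).
    """

    station: str
    species: GasSpecies
    flux: float  # mmol m^-2 d^-1
    k_i: float  # cm h^-1
    p_water: float  # uatm
    p_atm: float  # uatm
    k600_codes: tuple[str, ...] = ()
    n_exponent: float = -0.5

    def __post_init__(self) -> None:
        dp = self.p_water - self.p_atm
        if dp != 0 and self.flux != 0 and math.copysign(1, self.flux) != math.copysign(1, dp):
            raise DomainError(
                f"flux sign ({self.flux}) inconsistent with pressure "
                f"difference ({dp}) for station {self.station}"
            )


@dataclass(frozen=True)
class EbullitionRecord:
    """One inverted-funnel chamber deployment."""

    species: GasSpecies
    gas_concentration: float  # mg m^-3 (GC-measured concentration in collected gas)
    gas_volume_collected: float  # m^3 (water loss in the serum bottle)
    funnel_area: float  # m^2
    sampling_interval: float  # days

    def __post_init__(self) -> None:
        if self.funnel_area <= 0:
            raise DomainError(f"funnel_area={self.funnel_area!r} must be > 0")
        if self.sampling_interval <= 0:
            raise DomainError(
                f"sampling_interval={self.sampling_interval!r} must be > 0"
            )
        if self.gas_volume_collected < 0:
            raise DomainError(
                f"gas_volume_collected={self.gas_volume_collected!r} must be >= 0"
            )
        if self.gas_concentration < 0:
            raise DomainError(
                f"gas_concentration={self.gas_concentration!r} must be >= 0"
            )


@dataclass(frozen=True)
class EbullitionFlux:
    mg_m2_d: float
    mmol_m2_d: float


def ebullition_flux(r: EbullitionRecord) -> EbullitionFlux:
    """Chamber ebullition flux: conc x volume / (area x interval).

    Returned both on a mass basis (mg m^-2 d^-1, the chamber-native unit)
    and converted to mmol m^-2 d^-1 via the species molar mass.
    """
    mg = r.gas_concentration * r.gas_volume_collected / (
        r.funnel_area * r.sampling_interval
    )
    mmol = mg / r.species.molar_mass  # mg / (g mol^-1) = mmol
    return EbullitionFlux(mg_m2_d=mg, mmol_m2_d=mmol)


@dataclass(frozen=True)
class CampaignSummary:
    """Central value +/- sample std, range and n for one species' fluxes."""

    species: GasSpecies
    statistic: str  # "mean" | "median"
    central: float
    std: float
    minimum: float
    maximum: float
    n: int
    members: tuple[float, ...] = field(default=(), repr=False)


def aggregate_campaign(
    estimates: list[FluxEstimate], statistic: str = "mean"
) -> CampaignSummary:
    """Aggregate per-station fluxes of one species over a campaign.

    ``statistic`` selects the central value (mean or median); the spread is
    always the sample standard deviation, and the full range and member
    values are retained.
    """
    if not estimates:
        raise AggregationError("cannot aggregate an empty flux list")
    species = {e.species for e in estimates}
    if len(species) > 1:
        raise AggregationError(
            f"mixed species in one aggregation: {sorted(s.value for s in species)}"
        )
    values = np.array([e.flux for e in estimates], dtype=float)
    if statistic == "mean":
        central = float(values.mean())
    elif statistic == "median":
        central = float(np.median(values))
    else:
        raise AggregationError(f"unknown statistic {statistic!r}")
    std = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return CampaignSummary(
        species=next(iter(species)),
        statistic=statistic,
        central=central,
        std=std,
        minimum=float(values.min()),
        maximum=float(values.max()),
        n=len(values),
        members=tuple(float(v) for v in values),
    )
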