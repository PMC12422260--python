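"""Area-weighted catchment emission budget and source attribution.

The catchment total follows a surface-area-based approach: the mean areal
flux of each waterbody (reservoir, river, estuary) is multiplied by its
surface area, annualized over 365 days, converted to gas mass and expressed
as CO2-equivalents with a mass-basis global warming potential for CH4
(27, IPCC AR6 100-yr horizon).  Waterbody shares and the CO2/CH4 split of
the CO2-equivalent total are reported as percentages.

Source attribution partitions a waterbody's emission over segments labelled
with an anthropogenic source class (dam discharge, sand extraction, other),
summing per-station emissions within each class.

Headline percentages use round-half-up at the reported precision so that,
e.g., 0.075 Mmol d^-1 prints as 0.08 (bankers' rounding would give 0.07).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import AttributionError, BudgetError, DomainError
from .gas_physics import GasSpecies
from .units import DAYS_PER_YEAR, mmol_m2_d_to_mol_d, mol_yr_to_gg_yr

__all__ = [
    "GWP_CH4",
    "Segment",
    "WaterbodyGeometry",
    "TotalEmission",
    "BudgetTable",
    "round_half_up",
    "total_emission",
    "co2_equivalent",
    "molar_co2_equivalent",
    "catchment_budget",
    "source_attribution",
]

#: Mass-basis 100-yr global warming potential of CH4 (IPCC AR6).
GWP_CH4 = 27.0

WATERBODIES = ("reservoir", "river", "estuary")
SOURCE_CLASSES = ("dam_discharge", "sand_extraction", "other")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Segment:
    """A stretch of one waterbody attributed to a single source class."""

    segment_id: str
    stations: tuple[str, ...]
    source_class: str
    area_fraction: float

    def __post_init__(self) -> None:
        if self.source_class not in SOURCE_CLASSES:
            raise AttributionError(
                f"source_class={self.source_class!r} not in {SOURCE_CLASSES}"
            )
        if not 0 <= self.area_fraction <= 1:
            raise DomainError(
                f"area_fraction={self.area_fraction!r} outside [0, 1]"
            )


@dataclass(frozen=True)
class WaterbodyGeometry:
    """Surface area (km^2) and optional segment map of one waterbody."""

    name: str
    surface_area: float  # km^2
    segments: tuple[Segment, ...] = ()

    def __post_init__(self) -> None:
        if self.surface_area <= 0:
            raise DomainError(f"surface_area={self.surface_area!r} must be > 0")
        if self.segments:
            total = sum(s.area_fraction for s in self.segments)
            if abs(total - 1.0) > 1e-6:
                raise DomainError(
                    f"segment area fractions of {self.name!r} sum to {total}, not 1"
                )


@dataclass(frozen=True)
class TotalEmission:
    """Whole-waterbody emission of one gas on molar and mass scales."""

    mmol_m2_d: float
    megamol_per_day: float  # Mmol d^-1
    gg_gas_yr: float


def total_emission(
    areal_flux: float, area_km2: float, species: GasSpecies
) -> TotalEmission:
    """Scale an areal flux (mmol m^-2 d^-1) to a whole-waterbody emission.

    Exactly linear in both flux and area.  Returns Mmol d^-1 and, after
    annualization over 365 days, Gg of gas per year.
    """
    if area_km2 <= 0:
        raise DomainError(f"area_km2={area_km2!r} must be > 0")
    mol_per_day = mmol_m2_d_to_mol_d(areal_flux, area_km2)
    megamol_per_day = mol_per_day / 1e6
    gg = mol_yr_to_gg_yr(mol_per_day * DAYS_PER_YEAR, species.molar_mass)
    return TotalEmission(
        mmol_m2_d=areal_flux, megamol_per_day=megamol_per_day, gg_gas_yr=gg
    )


def co2_equivalent(
    mass_ch4_gg_yr: float, mass_co2_gg_yr: float, gwp: float = GWP_CH4
) -> tuple[float, dict[str, float]]:
    """CO2-equivalent total (Gg yr^-1) and the percent split per gas.

    Mass basis: CO2-eq = mass_CO2 + gwp * mass_CH4.
    """
    if mass_ch4_gg_yr < 0 or mass_co2_gg_yr < 0:
        raise DomainError("gas masses must be >= 0")
    total = mass_co2_gg_yr + gwp * mass_ch4_gg_yr
    if total == 0:
        split = {"CO2": 0.0, "CH4": 0.0}
    else:
        split = {
            "CO2": 100.0 * mass_co2_gg_yr / total,
            "CH4": 100.0 * gwp * mass_ch4_gg_yr / total,
        }
    return total, split


def molar_co2_equivalent(mol_ch4: float, gwp: float = GWP_CH4) -> float:
    """Molar bridge: mol CO2-eq per mol CH4 under a mass-basis GWP.

    1 mol CH4 = gwp * (M_CH4 / M_CO2) mol CO2-eq (~9.84 at gwp = 27).
    Provided for flux-space comparisons only; the headline budget is
    computed on the mass basis.
    """
    return mol_ch4 * gwp * GasSpecies.CH4.molar_mass / GasSpecies.CO2.molar_mass


@dataclass(frozen=True)
class BudgetTable:
    """Catchment budget: per-waterbody table plus catchment-level scalars."""

    table: pd.DataFrame  # one row per waterbody
    total_co2eq_gg_yr: float
    shares_pct: dict[str, float]  # waterbody -> % of CO2-eq total
    gas_split_pct: dict[str, float]  # gas -> % of CO2-eq total
    gwp: float = GWP_CH4
    attribution_pct: dict[str, dict[str, float]] = field(default_factory=dict)


def catchment_budget(
    areal_fluxes: dict[str, dict[str, float]],
    geometry: dict[str, WaterbodyGeometry],
    gwp: float = GWP_CH4,
) -> BudgetTable:
    """Assemble the catchment CO2-equivalent budget.

    ``areal_fluxes`` maps waterbody -> {"CO2": flux, "CH4": flux} in
    mmol m^-2 d^-1; ``geometry`` supplies surface areas.  Shares sum to
    100% by construction; missing waterbodies or species raise
    :class:`BudgetError` naming the gaps.
    """
    gaps = [
        f"{w}/{g.value}"
        for w in geometry
        for g in GasSpecies
        if g.value not in areal_fluxes.get(w, {})
    ]
    if gaps:
        raise BudgetError(f"missing areal fluxes for: {', '.join(gaps)}")

    rows = []
    for name, geom in geometry.items():
        em = {
            g: total_emission(areal_fluxes[name][g.value], geom.surface_area, g)
            for g in GasSpecies
        }
        co2eq, _ = co2_equivalent(
            em[GasSpecies.CH4].gg_gas_yr, em[GasSpecies.CO2].gg_gas_yr, gwp
        )
        rows.append(
            {
                "waterbody": name,
                "area_km2": geom.surface_area,
                "flux_co2_mmol_m2_d": areal_fluxes[name]["CO2"],
                "flux_ch4_mmol_m2_d": areal_fluxes[name]["CH4"],
                "co2_Mmol_d": em[GasSpecies.CO2].megamol_per_day,
                "ch4_Mmol_d": em[GasSpecies.CH4].megamol_per_day,
                "co2_gg_yr": em[GasSpecies.CO2].gg_gas_yr,
                "ch4_gg_yr": em[GasSpecies.CH4].gg_gas_yr,
                "co2eq_gg_yr": co2eq,
            }
        )
    table = pd.DataFrame(rows).set_index("waterbody")
    total = float(table["co2eq_gg_yr"].sum())
    if total <= 0:
        raise BudgetError("catchment CO2-equivalent total is non-positive")
    shares = {w: 100.0 * v / total for w, v in table["co2eq_gg_yr"].items()}
    _, split = co2_equivalent(
        float(table["ch4_gg_yr"].sum()), float(table["co2_gg_yr"].sum()), gwp
    )
    table["share_pct"] = [shares[w] for w in table.index]
    return BudgetTable(
        table=table,
        total_co2eq_gg_yr=total,
        shares_pct=shares,
        gas_split_pct=split,
        gwp=gwp,
    )


def source_attribution(
    station_fluxes: dict[str, float],
    segments: tuple[Segment, ...] | list[Segment],
    station_weights: dict[str, float] | None = None,
) -> dict[str, float]:
    """Percent of a waterbody's emission attributable to each source class.

    Every station must belong to exactly one segment; per-station area
    weights default to equal.  Segment emission is the weighted flux sum of
    its stations; class contributions are normalized to 100%.  Invariant to
    station ordering.
    """
    station_to_class: dict[str, str] = {}
    for seg in segments:
        for st in seg.stations:
            if st in station_to_class:
                raise AttributionError(f"station {st!r} mapped to multiple segments")
            station_to_class[st] = seg.source_class
    unmapped = sorted(set(station_fluxes) - set(station_to_class))
    if unmapped:
        raise AttributionError(f"stations without a source class: {unmapped}")

    weights = station_weights or {st: 1.0 for st in station_fluxes}
    class_sums = {c: 0.0 for c in SOURCE_CLASSES}
    for st, flux in station_fluxes.items():
        class_sums[station_to_class[st]] += weights.get(st, 1.0) * flux
    total = sum(class_sums.values())
    if total == 0:
        raise AttributionError("total emission is zero; attribution undefined")
    return {c: 100.0 * v / total for c, v in class_sums.items()}
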