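"""Published campaign-level summary statistics for the Kenyir Reservoir -
Terengganu River - estuary system, used as *inputs* to the catchment budget.

The station-level raw data of the field study are not distributed with the
package; what it ships are the campaign summary statistics the study
reports (seasonal reservoir flux means, river campaign medians and their
printed source-contribution percentages, estuary flow-regime means, and
digitized surface areas).  The budget machinery consumes these numbers
unchanged — nothing here is derived by the package.

Units: fluxes in mmol m^-2 d^-1, areas in km^2.
"""

from __future__ import annotations

from .budget import (
    BudgetTable,
    GWP_CH4,
    WaterbodyGeometry,
    catchment_budget,
)

__all__ = [
    "RESERVOIR_SEASONAL_FLUX",
    "RIVER_CAMPAIGNS",
    "ESTUARY_FLOW_REGIME_FLUX",
    "SURFACE_AREAS_KM2",
    "headline_areal_fluxes",
    "headline_budget",
    "average_contribution_pct",
]

#: Seasonal reservoir flux means (mmol m^-2 d^-1).
RESERVOIR_SEASONAL_FLUX = {
    "wet": {"CO2": 97.0, "CH4": 2.0},
    "dry": {"CO2": 54.0, "CH4": 0.8},
}

#: River longitudinal campaigns: median +/- std areal flux per gas and the
#: printed contribution percentages of each anthropogenic source class.
RIVER_CAMPAIGNS = {
    "Mar-18": {
        "CO2": {"median": 7.5, "std": 7.1,
                "contribution_pct": {"dam_discharge": 8, "sand_extraction": 49, "other": 43}},
        "CH4": {"median": 0.5, "std": 3.0,
                "contribution_pct": {"dam_discharge": 55, "sand_extraction": 38, "other": 7}},
    },
    "Apr-18": {
        "CO2": {"median": 26.0, "std": 42.0,
                "contribution_pct": {"dam_discharge": 10, "sand_extraction": 71, "other": 18}},
        "CH4": {"median": 1.0, "std": 5.7,
                "contribution_pct": {"dam_discharge": 16, "sand_extraction": 79, "other": 5}},
    },
    "Apr-19": {
        "CO2": {"median": 37.0, "std": 14.0,
                "contribution_pct": {"dam_discharge": 24, "sand_extraction": 32, "other": 45}},
        "CH4": {"median": 0.3, "std": 0.4,
                "contribution_pct": {"dam_discharge": 18, "sand_extraction": 47, "other": 35}},
    },
}

#: Estuary campaign flux means by flow regime (mmol m^-2 d^-1).
ESTUARY_FLOW_REGIME_FLUX = {
    "high_flow": {"CO2": 20.0, "CH4": 13.0},
    "low_flow": {"CO2": 232.0, "CH4": 4.1},
}

#: Digitized surface areas (km^2).
SURFACE_AREAS_KM2 = {"reservoir": 369.0, "river": 10.0, "estuary": 7.6}


def _mean(values) -> float:
    values = list(values)
    return sum(values) / len(values)


def headline_areal_fluxes() -> dict[str, dict[str, float]]:
    """Per-waterbody mean areal fluxes feeding the headline budget.

    Recipe: plain mean of the wet/dry reservoir means, mean of the three
    river campaign medians, mean of the high/low-flow estuary means.
    """
    return {
        "reservoir": {
            gas: _mean(s[gas] for s in RESERVOIR_SEASONAL_FLUX.values())
            for gas in ("CO2", "CH4")
        },
        "river": {
            gas: _mean(c[gas]["median"] for c in RIVER_CAMPAIGNS.values())
            for gas in ("CO2", "CH4")
        },
        "estuary": {
            gas: _mean(r[gas] for r in ESTUARY_FLOW_REGIME_FLUX.values())
            for gas in ("CO2", "CH4")
        },
    }


def headline_budget(gwp: float = GWP_CH4) -> BudgetTable:
    """The catchment CO2-equivalent budget from the published summaries."""
    geometry = {
        name: WaterbodyGeometry(name=name, surface_area=area)
        for name, area in SURFACE_AREAS_KM2.items()
    }
    return catchment_budget(headline_areal_fluxes(), geometry, gwp=gwp)


def average_contribution_pct(gas: str) -> dict[str, float]:
    """Mean of the per-campaign source contributions for one gas (%)."""
    return {
        source: _mean(
            c[gas]["contribution_pct"][source] for c in RIVER_CAMPAIGNS.values()
        )
        for source in ("dam_discharge", "sand_extraction", "other")
    }
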