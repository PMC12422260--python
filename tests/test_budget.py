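"""Catchment budget arithmetic: totals, CO2-equivalents, shares, attribution."""

import numpy as np
import pytest

from ghgflux.budget import (
    GWP_CH4,
    Segment,
    WaterbodyGeometry,
    catchment_budget,
    co2_equivalent,
    molar_co2_equivalent,
    round_half_up,
    source_attribution,
    total_emission,
)
from ghgflux.errors import AttributionError, BudgetError, DomainError
from ghgflux.gas_physics import GasSpecies

# --- rounding -------------------------------------------------------------


@pytest.mark.parametrize(
    "x,ndigits,expected",
    [(0.075, 2, 0.08), (0.5, 0, 1.0), (50.6667, 0, 51.0), (35.3333, 0, 35.0), (2.5, 0, 3.0)],
)
def test_round_half_up_pinned(x, ndigits, expected):
    assert round_half_up(x, ndigits) == expected


# --- total emission -------------------------------------------------------


def test_river_total_emission_mar18():
    """Median flux 7.5 mmol/m2/d over 10 km2 -> 0.075 Mmol/d (prints 0.08)."""
    em = total_emission(7.5, 10.0, GasSpecies.CO2)
    assert em.megamol_per_day == pytest.approx(0.075, rel=1e-12)
    assert round_half_up(em.megamol_per_day, 2) == 0.08


def test_zero_flux_zero_emission():
    em = total_emission(0.0, 369.0, GasSpecies.CO2)
    assert em.megamol_per_day == 0.0
    assert em.gg_gas_yr == 0.0


def test_reservoir_annual_mass_hand_chain():
    """75.5 mmol CO2 m-2 d-1 over 369 km2 ~ 447 Gg CO2 / yr."""
    expected = 75.5e-3 * 369e6 * 365 * 44.01 / 1e9
    em = total_emission(75.5, 369.0, GasSpecies.CO2)
    assert em.gg_gas_yr == pytest.approx(expected, rel=1e-12)
    assert em.gg_gas_yr == pytest.approx(447.0, rel=0.01)


def test_total_emission_linear_in_flux_and_area(rng):
    for _ in range(50):
        f, a, s = rng.uniform(0.1, 100), rng.uniform(0.1, 500), rng.uniform(1.5, 4)
        base = total_emission(f, a, GasSpecies.CH4).gg_gas_yr
        assert total_emission(s * f, a, GasSpecies.CH4).gg_gas_yr == pytest.approx(
            s * base, rel=1e-12
        )
        assert total_emission(f, s * a, GasSpecies.CH4).gg_gas_yr == pytest.approx(
            s * base, rel=1e-12
        )


def test_nonpositive_area_rejected():
    with pytest.raises(DomainError):
        total_emission(1.0, 0.0, GasSpecies.CO2)


# --- CO2 equivalents ------------------------------------------------------


def test_gwp_mass_basis():
    total, split = co2_equivalent(1.0, 0.0)
    assert total == pytest.approx(27.0)
    assert split["CH4"] == pytest.approx(100.0)


def test_pure_co2_passthrough():
    total, split = co2_equivalent(0.0, 42.0)
    assert total == pytest.approx(42.0)
    assert split["CO2"] == pytest.approx(100.0)


def test_molar_bridge():
    """1 mol CH4 = 27 * 16.04/44.01 ~ 9.84 mol CO2-eq."""
    assert molar_co2_equivalent(1.0) == pytest.approx(27 * 16.04 / 44.01, rel=1e-12)
    assert molar_co2_equivalent(1.0) == pytest.approx(9.84, abs=0.01)


# --- catchment budget -----------------------------------------------------


def _geometry(areas):
    return {
        name: WaterbodyGeometry(name=name, surface_area=a) for name, a in areas.items()
    }


def test_equal_fluxes_shares_follow_areas():
    fluxes = {w: {"CO2": 10.0, "CH4": 0.0} for w in ("reservoir", "river", "estuary")}
    bt = catchment_budget(
        fluxes, _geometry({"reservoir": 1.0, "river": 1.0, "estuary": 2.0})
    )
    assert bt.shares_pct["reservoir"] == pytest.approx(25.0)
    assert bt.shares_pct["river"] == pytest.approx(25.0)
    assert bt.shares_pct["estuary"] == pytest.approx(50.0)
    assert sum(bt.shares_pct.values()) == pytest.approx(100.0, abs=0.1)


def test_shares_invariant_under_uniform_flux_rescale():
    fluxes = {
        "reservoir": {"CO2": 75.5, "CH4": 1.4},
        "river": {"CO2": 23.5, "CH4": 0.6},
        "estuary": {"CO2": 126.0, "CH4": 8.55},
    }
    geom = _geometry({"reservoir": 369.0, "river": 10.0, "estuary": 7.6})
    a = catchment_budget(fluxes, geom)
    scaled = {w: {g: 3.7 * v for g, v in d.items()} for w, d in fluxes.items()}
    b = catchment_budget(scaled, geom)
    for w in fluxes:
        assert a.shares_pct[w] == pytest.approx(b.shares_pct[w], rel=1e-12)


def test_co2eq_total_additive_over_waterbodies_and_gases():
    fluxes = {
        "reservoir": {"CO2": 10.0, "CH4": 1.0},
        "river": {"CO2": 5.0, "CH4": 0.5},
        "estuary": {"CO2": 2.0, "CH4": 0.2},
    }
    geom = _geometry({"reservoir": 10.0, "river": 5.0, "estuary": 2.0})
    bt = catchment_budget(fluxes, geom)
    componentwise = float(
        (bt.table["co2_gg_yr"] + GWP_CH4 * bt.table["ch4_gg_yr"]).sum()
    )
    assert bt.total_co2eq_gg_yr == pytest.approx(componentwise, rel=1e-12)


def test_missing_waterbody_flux_names_gap():
    geom = _geometry({"reservoir": 1.0, "river": 1.0})
    with pytest.raises(BudgetError, match="river/CH4"):
        catchment_budget(
            {"reservoir": {"CO2": 1.0, "CH4": 1.0}, "river": {"CO2": 1.0}}, geom
        )


# --- source attribution ---------------------------------------------------


def _segments():
    return (
        Segment("upper", ("L1", "L2"), "dam_discharge", 0.4),
        Segment("middle", ("L3", "L4"), "sand_extraction", 0.4),
        Segment("lower", ("L5",), "other", 0.2),
    )


def test_single_class_is_100_percent():
    attr = source_attribution(
        {"L1": 2.0, "L2": 3.0},
        (Segment("all", ("L1", "L2"), "dam_discharge", 1.0),),
    )
    assert attr["dam_discharge"] == pytest.approx(100.0)
    assert sum(attr.values()) == pytest.approx(100.0, abs=0.1)


def test_attribution_invariant_to_station_order():
    fluxes = {"L1": 1.0, "L2": 2.0, "L3": 3.0, "L4": 4.0, "L5": 5.0}
    a = source_attribution(fluxes, _segments())
    b = source_attribution(dict(reversed(list(fluxes.items()))), _segments())
    assert a == b


def test_unmapped_station_rejected():
    with pytest.raises(AttributionError, match="L9"):
        source_attribution({"L1": 1.0, "L9": 1.0}, _segments()[:1])


def test_printed_campaign_contribution_averages():
    """Means of the three published CO2 campaign rows (8/49/43, 10/71/18,
    24/32/45) give 14/51/35 after integer round-half-up; CH4 gives 30/55."""
    co2_rows = np.array([[8, 49, 43], [10, 71, 18], [24, 32, 45]], dtype=float)
    means = co2_rows.mean(axis=0)
    rounded = [round_half_up(m) for m in means]
    assert rounded == [14, 51, 35]
    ch4_rows = np.array([[55, 38, 7], [16, 79, 5], [18, 47, 35]], dtype=float)
    ch4_means = ch4_rows.mean(axis=0)
    assert round_half_up(ch4_means[0]) == 30
    assert round_half_up(ch4_means[1]) == 55


def test_segment_fraction_validation():
    with pytest.raises(DomainError, match="fractions"):
        WaterbodyGeometry(
            name="river",
            surface_area=10.0,
            segments=(Segment("a", ("L1",), "other", 0.5),),
        )
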