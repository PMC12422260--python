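"""Unit conversion factors and the helpers that own them.

Every numeric conversion factor used by the package lives here, stated
once, so the flux and budget arithmetic contains no inline magic numbers.
All internal gas amounts are mol-based; mass (g, Gg) appears only at the
budget boundary.
"""

from __future__ import annotations

# --- fundamental constants -------------------------------------------------
CELSIUS_ZERO_K = 273.15
#: Ideal gas constant in L atm mol^-1 K^-1 (headspace phase partitioning).
R_L_ATM = 0.0820574
#: Ideal-gas molar volume at STP, L mol^-1 (Bunsen coefficient -> mol L^-1 atm^-1).
MOLAR_VOLUME_STP_L = 22.414

# --- simple scale factors --------------------------------------------------
CM_PER_M = 100.0
HOURS_PER_DAY = 24.0
UATM_PER_ATM = 1e6
UMOL_PER_MOL = 1e6
MMOL_PER_MOL = 1e3
L_PER_M3 = 1e3
ML_PER_L = 1e3
M2_PER_KM2 = 1e6
G_PER_GG = 1e9
MOL_PER_MMOL = 1e-3
DAYS_PER_YEAR = 365.0

#: Collapsed factor of the diffusive-flux unit chain:
#: k [cm h^-1] * K [mol L^-1 atm^-1] * dp [uatm]  ->  flux [mmol m^-2 d^-1].
#: Derivation: (1/CM_PER_M) * HOURS_PER_DAY * L_PER_M3 * (1/UATM_PER_ATM)
#:             * MMOL_PER_MOL = 0.24.  Validated against the long-form chain
#: in the test suite.
DIFFUSIVE_FLUX_FACTOR = (
    (1.0 / CM_PER_M) * HOURS_PER_DAY * L_PER_M3 * (1.0 / UATM_PER_ATM) * MMOL_PER_MOL
)


def kelvin(temperature_c: float) -> float:
    """Convert a Celsius temperature to kelvin."""
    return temperature_c + CELSIUS_ZERO_K


def mmol_m2_d_to_mol_d(areal_flux: float, area_km2: float) -> float:
    """Total molar emission (mol d^-1) of an areal flux over a surface area."""
    return areal_flux * MOL_PER_MMOL * area_km2 * M2_PER_KM2


def mol_yr_to_gg_yr(mol_per_year: float, molar_mass: float) -> float:
    """Convert an annual molar emission to gigagrams of gas per year."""
    return mol_per_year * molar_mass / G_PER_GG
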