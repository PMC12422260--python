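"""Solubility, Schmidt numbers, and concentration/partial-pressure conversions.

Supports the two greenhouse gases of interest in surface freshwater to
estuarine salinities (0-36): CO2 and CH4.

Solubility formulations are not dictated by the flux equation itself, so the
package adopts the community standards and flags them prominently: the
Weiss (1974) mol L^-1 atm^-1 fit for CO2 and the Wiesenburg & Guinasso
(1979) Bunsen-coefficient fit for CH4 (converted with the ideal molar
volume).  Both coefficient sets ship in a plain-text table
(``data/solubility_coefficients.csv``) with citation strings and can be
overridden at load time.

Schmidt numbers use the cubic temperature polynomial

    Sc(t) = A - B t + C t^2 - D t^3     (t in deg C, valid 0-30 deg C)

with the Wanninkhof (1992) coefficient sets for fresh water and 35-salinity
seawater; intermediate salinities are linearly interpolated between the two
endmembers.  Sc(CO2, fresh, 20 deg C) = 599.4, the anchor of the k600
convention.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import DomainError
from .units import MOLAR_VOLUME_STP_L, kelvin

__all__ = [
    "GasSpecies",
    "WaterState",
    "SchmidtCoefficients",
    "solubility",
    "schmidt_number",
    "concentration_to_partial_pressure",
    "partial_pressure_to_concentration",
    "load_solubility_table",
    "load_schmidt_table",
    "SCHMIDT_T_RANGE",
]

#: Validity range (deg C) of the cubic Schmidt polynomial fits.
SCHMIDT_T_RANGE = (0.0, 30.0)

_MOLAR_MASS = {"CO2": 44.01, "CH4": 16.04}


class GasSpecies(enum.Enum):
    """The two gases handled by the pipeline."""

    CO2 = "CO2"
    CH4 = "CH4"

    @property
    def molar_mass(self) -> float:
        """Molar mass in g mol^-1."""
        return _MOLAR_MASS[self.value]


@dataclass(frozen=True)
class WaterState:
    """Temperature (deg C) and practical salinity of a water parcel.

    Ranges reflect tropical surface-to-hypolimnion waters: temperature in
    [0, 40] deg C and salinity in [0, 36].
    """

    temperature: float
    salinity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature <= 40.0:
            raise DomainError(
                f"temperature={self.temperature!r} outside [0, 40] deg C"
            )
        if not 0.0 <= self.salinity <= 36.0:
            raise DomainError(f"salinity={self.salinity!r} outside [0, 36]")


@dataclass(frozen=True)
class SchmidtCoefficients:
    """Cubic polynomial coefficients for one species in one medium."""

    species: GasSpecies
    medium: str  # "fresh" or "seawater35"
    A: float
    B: float
    C: float
    D: float
    citation: str = ""

    def evaluate(self, temperature_c: float) -> float:
        t = temperature_c
        return self.A - self.B * t + self.C * t**2 - self.D * t**3


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ghgflux.data").joinpath(name)))


def load_solubility_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the solubility coefficient table (overridable via ``path``)."""
    df = pd.read_csv(path if path is not None else _data_path("solubility_coefficients.csv"))
    return df.set_index("species")


def load_schmidt_table(path: str | Path | None = None) -> Mapping[tuple[str, str], SchmidtCoefficients]:
    """Load Schmidt coefficients keyed by (species name, medium)."""
    df = pd.read_csv(path if path is not None else _data_path("schmidt_coefficients.csv"))
    table = {}
    for row in df.itertuples(index=False):
        table[(row.species, row.medium)] = SchmidtCoefficients(
            species=GasSpecies(row.species),
            medium=row.medium,
            A=row.A,
            B=row.B,
            C=row.C,
            D=row.D,
            citation=row.citation,
        )
    return table


_SOLUBILITY = load_solubility_table()
_SCHMIDT = load_schmidt_table()


def solubility(
    species: GasSpecies,
    state: WaterState,
    table: pd.DataFrame | None = None,
) -> float:
    """Solubility constant K in mol L^-1 atm^-1.

    Both fits share the functional form

        ln X = a1 + a2 (100/T) + a3 ln(T/100)
               + S [b1 + b2 (T/100) + b3 (T/100)^2]

    with T in kelvin and S the salinity.  For CO2 the fit yields K
    directly (``ln_k0``); for CH4 it yields the Bunsen coefficient
    (``ln_bunsen``), divided here by the 22.414 L mol^-1 ideal molar
    volume.  K decreases with both temperature and salinity
    (salting out).
    """
    tab = table if table is not None else _SOLUBILITY
    row = tab.loc[species.value]
    T = kelvin(state.temperature)
    s = state.salinity
    ln_x = (
        row["a1"]
        + row["a2"] * (100.0 / T)
        + row["a3"] * math.log(T / 100.0)
        + s * (row["b1"] + row["b2"] * (T / 100.0) + row["b3"] * (T / 100.0) ** 2)
    )
    x = math.exp(ln_x)
    if row["form"] == "ln_bunsen":
        return x / MOLAR_VOLUME_STP_L
    if row["form"] == "ln_k0":
        return x
    raise DomainError(f"unknown solubility form {row['form']!r} for {species.value}")


def schmidt_number(
    species: GasSpecies,
    state: WaterState,
    table: Mapping[tuple[str, str], SchmidtCoefficients] | None = None,
) -> float:
    """Schmidt number (dimensionless) at the given temperature and salinity.

    Temperatures outside the 0-30 deg C fit range are clamped to the nearest
    bound with a warning rather than extrapolating the cubic (tropical
    surface waters reach 30.5 deg C; cubic extrapolation misbehaves).
    Salinities between the fresh (0) and seawater (35) coefficient sets are
    linearly interpolated; salinities above 35 use the seawater set.
    """
    tab = table if table is not None else _SCHMIDT
    lo, hi = SCHMIDT_T_RANGE
    t = state.temperature
    if t < lo or t > hi:
        warnings.warn(
            f"temperature {t} deg C outside Schmidt fit range [{lo}, {hi}]; "
            "clamped",
            stacklevel=2,
        )
        t = min(max(t, lo), hi)
    sc_fresh = tab[(species.value, "fresh")].evaluate(t)
    if state.salinity == 0.0:
        return sc_fresh
    sc_sea = tab[(species.value, "seawater35")].evaluate(t)
    w = min(state.salinity / 35.0, 1.0)
    return (1.0 - w) * sc_fresh + w * sc_sea


def concentration_to_partial_pressure(
    concentration_um: float, species: GasSpecies, state: WaterState
) -> float:
    """Partial pressure (uatm) of a dissolved concentration (umol L^-1).

    With K in mol L^-1 atm^-1 the scaling factors cancel:
    umol L^-1 / (mol L^-1 atm^-1) = uatm.
    """
    if concentration_um < 0:
        raise DomainError(f"concentration={concentration_um!r} must be >= 0")
    return concentration_um / solubility(species, state)


def partial_pressure_to_concentration(
    partial_pressure_uatm: float, species: GasSpecies, state: WaterState
) -> float:
    """Inverse of :func:`concentration_to_partial_pressure` (exact)."""
    if partial_pressure_uatm < 0:
        raise DomainError(f"partial_pressure={partial_pressure_uatm!r} must be >= 0")
    return partial_pressure_uatm * solubility(species, state)
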