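"""Headspace-equilibration back-calculation of dissolved gas concentrations.

Field protocol: a 60 mL serum bottle of sample water has one third of the
water displaced by helium; after equilibration at lab temperature the
headspace mole fraction (ppm) is measured by gas chromatography.  The
original dissolved concentration is recovered by mass balance over the
two phases:

    n_total = n_headspace + n_aqueous
            = p * V_h / (R T)  +  K(T, S) * p * V_w
    C_original = n_total / V_w

where p is the equilibrium partial pressure implied by the GC readout,
V_h and V_w the headspace and water volumes, and K the solubility constant
at the equilibration state.  Ideal-gas behaviour is assumed in the
headspace (uatm regime; fugacity corrections are below 1% and ignored).
The forward equilibration simulator (:func:`equilibrate`) is a first-class
operation: the synthetic module and the round-trip tests both need it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import DomainError
from .gas_physics import GasSpecies, WaterState, solubility
from .units import ML_PER_L, R_L_ATM, UATM_PER_ATM, UMOL_PER_MOL, kelvin

__all__ = ["HeadspaceMeasurement", "dissolved_concentration", "equilibrate"]

#: Lab equilibration temperature when the record does not state one, deg C.
DEFAULT_EQUILIBRATION_T = 25.0


@dataclass(frozen=True)
class HeadspaceMeasurement:
    """One equilibrated serum bottle as read by the GC.

    ``headspace_mole_fraction`` is the calibrated GC readout in ppm of the
    headspace gas; ``headspace_fraction`` is the volume fraction of the
    bottle occupied by helium (1/3 in the field protocol).
    """

    species: GasSpecies
    headspace_mole_fraction: float  # ppm
    equilibration_temperature: float = DEFAULT_EQUILIBRATION_T  # deg C
    equilibration_salinity: float = 0.0
    bottle_volume: float = 60.0  # mL
    headspace_fraction: float = 1.0 / 3.0
    ambient_pressure: float = 1.0  # atm

    def __post_init__(self) -> None:
        if not 0.0 < self.headspace_fraction < 1.0:
            raise DomainError(
                f"headspace_fraction={self.headspace_fraction!r} is a "
                "degenerate geometry; must be strictly between 0 and 1"
            )
        if self.bottle_volume <= 0:
            raise DomainError(f"bottle_volume={self.bottle_volume!r} must be > 0")
        if self.headspace_mole_fraction < 0:
            raise DomainError(
                f"headspace_mole_fraction={self.headspace_mole_fraction!r} must be >= 0"
            )
        if self.ambient_pressure <= 0:
            raise DomainError(f"ambient_pressure={self.ambient_pressure!r} must be > 0")

    @property
    def headspace_volume_l(self) -> float:
        return self.bottle_volume * self.headspace_fraction / ML_PER_L

    @property
    def water_volume_l(self) -> float:
        return self.bottle_volume * (1.0 - self.headspace_fraction) / ML_PER_L


def _equilibrium_state(m: HeadspaceMeasurement) -> WaterState:
    return WaterState(m.equilibration_temperature, m.equilibration_salinity)


def dissolved_concentration(m: HeadspaceMeasurement) -> float:
    """Original dissolved concentration (umol L^-1) before headspacing.

    Linear in the GC readout and monotone in the headspace fraction:
    the larger the helium volume, the more analyte a given ppm represents.
    """
    p_atm = m.headspace_mole_fraction / UATM_PER_ATM * m.ambient_pressure
    k = solubility(m.species, _equilibrium_state(m))
    t_k = kelvin(m.equilibration_temperature)
    n_headspace = p_atm * m.headspace_volume_l / (R_L_ATM * t_k)  # mol
    n_aqueous = k * p_atm * m.water_volume_l  # mol
    return (n_headspace + n_aqueous) / m.water_volume_l * UMOL_PER_MOL


def equilibrate(
    concentration_um: float,
    species: GasSpecies,
    equilibration_temperature: float = DEFAULT_EQUILIBRATION_T,
    equilibration_salinity: float = 0.0,
    bottle_volume: float = 60.0,
    headspace_fraction: float = 1.0 / 3.0,
    ambient_pressure: float = 1.0,
) -> HeadspaceMeasurement:
    """Forward-simulate equilibration of a known sample.

    Partitions the total analyte of a water sample of concentration
    ``concentration_um`` (umol L^-1) between headspace and aqueous phase by
    Henry's law at the equilibration state and returns the measurement the
    GC would report.  Exact inverse of :func:`dissolved_concentration`.
    """
    if concentration_um < 0:
        raise DomainError(f"concentration={concentration_um!r} must be >= 0")
    template = HeadspaceMeasurement(
        species=species,
        headspace_mole_fraction=0.0,
        equilibration_temperature=equilibration_temperature,
        equilibration_salinity=equilibration_salinity,
        bottle_volume=bottle_volume,
        headspace_fraction=headspace_fraction,
        ambient_pressure=ambient_pressure,
    )
    k = solubility(species, _equilibrium_state(template))
    t_k = kelvin(equilibration_temperature)
    v_h = template.headspace_volume_l
    v_w = template.water_volume_l
    n_total = concentration_um / UMOL_PER_MOL * v_w  # mol
    # n_total = p (V_h/(R T) + K V_w)  ->  solve for p
    p_atm = n_total / (v_h / (R_L_ATM * t_k) + k * v_w)
    ppm = p_atm / ambient_pressure * UATM_PER_ATM
    return replace(template, headspace_mole_fraction=ppm)
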