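"""Physical constants used throughout the simulation.

Units follow detector-physics convention: energies in MeV for particles and
eV for optical photons, lengths in mm, times in ns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Electron rest energy, MeV.
ELECTRON_MASS_MEV = 0.511

#: Fine-structure constant (dimensionless).
FINE_STRUCTURE = 1.0 / 137.035999

#: h*c in eV*nm.
HC_EV_NM = 1239.841984

#: Vacuum speed of light, mm/ns.
C_VACUUM_MM_NS = 299.792458

#: Frank-Tamm prefactor 2*pi*alpha*z^2/(h*c) for z=1, in photons/(eV*mm).
#: 2*pi*alpha/(hc) with hc in eV*nm gives photons/(eV*nm); 1 mm = 1e6 nm.
FRANK_TAMM_PREFACTOR = 2.0 * math.pi * FINE_STRUCTURE / HC_EV_NM * 1.0e6


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the constants entering the emission and transport physics."""

    electron_rest_energy_mev: float = ELECTRON_MASS_MEV
    fine_structure: float = FINE_STRUCTURE
    frank_tamm_prefactor_per_ev_mm: float = FRANK_TAMM_PREFACTOR
    light_speed_mm_ns: float = C_VACUUM_MM_NS

    def __post_init__(self) -> None:
        for name in (
            "electron_rest_energy_mev",
            "fine_structure",
            "frank_tamm_prefactor_per_ev_mm",
            "light_speed_mm_ns",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")


def wavelength_nm_to_ev(wavelength_nm: float) -> float:
    """Convert an optical wavelength in nm to photon energy in eV."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return HC_EV_NM / wavelength_nm


def ev_to_wavelength_nm(energy_ev: float) -> float:
    """Convert a photon energy in eV to wavelength in nm."""
    if energy_ev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_EV_NM / energy_ev
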