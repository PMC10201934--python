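"""Electron energy-loss and range tables.

The continuous slowing-down of the recoil electron is described by an
analytic Berger-Seltzer (ICRU-37) collision stopping power plus a small
approximate bremsstrahlung term.  Both are integrated once per material
into log-spaced energy-loss and CSDA-range tables, which the stepping
algorithm then interpolates -- the same initialize-once / interpolate-during
arrangement the full toolkit uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ELECTRON_MASS_MEV
from .materials import Material

__all__ = [
    "collision_stopping_power",
    "radiative_stopping_power",
    "LossTables",
    "build_loss_tables",
    "csda_range",
    "ke_after_path",
]

# Coefficient 2*pi*r_e^2*m*c^2*N_A = 0.153536 MeV cm^2/mol in the Bethe formula.
_K_MEV_CM2_PER_MOL = 0.153536

#: Scale (MeV) in the approximate radiative/collision ratio ~ Z_eff*E/800.
_RADIATIVE_SCALE_MEV = 800.0

#: Lowest tabulated kinetic energy; tracking stops here.
KE_MIN_MEV = 1e-3


def collision_stopping_power(mat: Material, ke: float, density_effect: bool = False) -> float:
    """Collision (ionisation) stopping power in MeV/mm at kinetic energy ``ke``.

    Berger-Seltzer formula for electrons (Moller-corrected Bethe) with the
    material's Bragg-rule mean excitation energy.  The density-effect
    correction is omitted by default; below ~1 MeV it is a sub-percent
    effect in BGO.
    """
    if ke < KE_MIN_MEV:
        raise ValueError(f"kinetic energy {ke} MeV below tabulation minimum {KE_MIN_MEV} MeV")
    m = ELECTRON_MASS_MEV
    tau = ke / m
    gamma = 1.0 + tau
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    i_ratio = mat.mean_excitation_ev * 1e-6 / m  # I in MeV over m
    log_term = math.log(tau * tau * (tau + 2.0) / (2.0 * i_ratio * i_ratio))
    f_minus = (
        1.0
        - beta2
        + (tau * tau / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / ((tau + 1.0) ** 2)
    )
    delta = 0.0
    if density_effect:
        # Sternheimer-Peierls general formula would go here; at the sub-MeV
        # energies of this study the correction is negligible and omitted.
        delta = 0.0
    bracket = log_term + f_minus - delta
    mass_sp = _K_MEV_CM2_PER_MOL / beta2 * mat.z_over_a * bracket  # MeV cm^2/g
    return mass_sp * mat.density / 10.0  # MeV/mm


def radiative_stopping_power(mat: Material, ke: float) -> float:
    """Approximate bremsstrahlung stopping power in MeV/mm.

    Uses the standard rule of thumb S_rad/S_col ~ Z_eff * E_total / 800 MeV,
    a <10% correction to the total below 1 MeV even in high-Z media.
    """
    if ke <= 0.0:
        return 0.0
    e_total = ke + ELECTRON_MASS_MEV
    ratio = mat.z_eff_bremsstrahlung * e_total / _RADIATIVE_SCALE_MEV
    return collision_stopping_power(mat, max(ke, KE_MIN_MEV)) * ratio


@dataclass
class LossTables:
    """Tabulated total stopping power and CSDA range for one material.

    ``csda_range`` is the cumulative integral of dE/(dE/dx) from the grid
    minimum (1 keV); the residual range below 1 keV (tens of nm) is dropped.
    """

    material_name: str
    ke_grid: np.ndarray  # MeV, log-spaced ascending
    dedx: np.ndarray  # MeV/mm
    csda_range: np.ndarray  # mm

    def __post_init__(self) -> None:
        if np.any(self.dedx <= 0.0):
            raise ValueError("stopping power must be positive everywhere")
        if np.any(np.diff(self.csda_range) <= 0.0):
            raise ValueError("CSDA range must be strictly increasing")
        self._log_ke = np.log(self.ke_grid)

    @property
    def ke_min(self) -> float:
        return float(self.ke_grid[0])

    @property
    def ke_max(self) -> float:
        return float(self.ke_grid[-1])

    def _check(self, ke: float) -> None:
        if ke < self.ke_min * (1.0 - 1e-12) or ke > self.ke_max * (1.0 + 1e-12):
            raise ValueError(f"kinetic energy {ke} MeV outside table span")

    def dedx_at(self, ke: float) -> float:
        self._check(ke)
        return float(np.interp(math.log(ke), self._log_ke, self.dedx))

    def range_at(self, ke: float) -> float:
        self._check(ke)
        return float(np.interp(math.log(ke), self._log_ke, self.csda_range))

    def ke_at_range(self, r: float) -> float:
        """Inverse of the range table; clamps to the grid minimum energy."""
        if r <= self.csda_range[0]:
            return self.ke_min
        if r >= self.csda_range[-1]:
            return self.ke_max
        return float(math.exp(np.interp(r, self.csda_range, self._log_ke)))

    def ke_after_path(self, ke: float, s: float) -> float:
        """Kinetic energy after travelling path length ``s`` (mm).

        Monotone interpolation of the range table and its inverse; a path
        beyond the remaining range clamps to the grid-minimum energy.
        """
        if s < 0:
            raise ValueError("path length must be non-negative")
        if s == 0.0:
            return ke
        return self.ke_at_range(self.range_at(ke) - s)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"ke_mev": self.ke_grid, "dedx_mev_per_mm": self.dedx, "csda_range_mm": self.csda_range}
        ).to_csv(path, index=False)


def build_loss_tables(
    mat: Material,
    ke_min: float = KE_MIN_MEV,
    ke_max: float = 2.0,
    n_points: int = 200,
) -> LossTables:
    """Build dE/dx and CSDA-range tables on a log grid (1 keV - 2 MeV default)."""
    grid = np.geomspace(ke_min, ke_max, n_points)
    dedx = np.array(
        [collision_stopping_power(mat, ke) + radiative_stopping_power(mat, ke) for ke in grid]
    )
    # cumulative trapezoid of dE / (dE/dx)
    inv = 1.0 / dedx
    dke = np.diff(grid)
    seg = 0.5 * (inv[1:] + inv[:-1]) * dke
    rng = np.concatenate([[0.0], np.cumsum(seg)])
    # strictly-increasing guard against any degenerate grid spacing
    rng = np.maximum.accumulate(rng + np.arange(len(rng)) * 1e-15)
    return LossTables(material_name=mat.name, ke_grid=grid, dedx=dedx, csda_range=rng)


def csda_range(tables: LossTables, ke: float) -> float:
    """CSDA range (mm) at kinetic energy ``ke``."""
    return tables.range_at(ke)


def ke_after_path(tables: LossTables, ke: float, s: float) -> float:
    """Kinetic energy after a path ``s`` mm, via the inverse range table."""
    return tables.ke_after_path(ke, s)
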