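"""Cerenkov (and optional scintillation) photon generation along electron steps.

The number of Cerenkov photons per unit path follows the Frank-Tamm
spectrum integrated over the material's optical window,

    dN/dl = (2*pi*alpha/hc) * integral_{eps_min}^{eps_max} (1 - 1/(beta^2 n^2(eps))) deps,

with negative integrand values clamped to zero (sub-threshold photon
energies contribute nothing).  Per step the photon count is Poisson with a
mean proportional to the step length, photons are placed evenly along the
rectilinear step, and each photon leaves on a cone at cos(theta) =
1/(beta*n(eps)) about the electron direction.

Three per-step yield conventions are provided (``mode``):

* ``"local"`` (default): the velocity is interpolated linearly between the
  step endpoints at each photon's position; the expected count is the
  trapezoid average of the endpoint yields.  Subdivision-invariant; the
  physically consistent choice for fine steps.
* ``"mean-beta"``: a single velocity beta = (beta_pre + beta_post)/2 is used
  for the count and all photon properties.  This mimics the coarse-step
  behaviour of production Monte Carlo toolkits and reproduces the downward
  bias of the photon count for range-sized steps.
* ``"pre"``: pre-step velocity only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import FRANK_TAMM_PREFACTOR, wavelength_nm_to_ev
from .materials import OpticalDispersion
from .transport import ElectronStep, ElectronTrack

__all__ = [
    "OpticalPhoton",
    "yield_per_mm",
    "CerenkovSampler",
    "expected_photons",
    "emit_cherenkov",
    "emit_for_track",
    "emit_scintillation",
    "assign_orders",
]

YIELD_MODES = ("local", "mean-beta", "pre")


@dataclass
class OpticalPhoton:
    """An emitted optical photon."""

    origin: np.ndarray  # mm
    emission_time: float  # ns
    energy_ev: float
    direction: np.ndarray  # unit vector
    kind: str  # "cerenkov" | "scintillation"
    order: int = 0  # emission index within the parent event, 1 = first


def yield_per_mm(beta: float, dispersion: OpticalDispersion) -> float:
    """Frank-Tamm photon yield per mm of path at velocity ``beta``.

    Trapezoid integral of the clamped integrand on the dispersion grid;
    exactly zero at or below the threshold beta = 1/max(n).
    """
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must lie strictly between 0 and 1")
    integrand = 1.0 - 1.0 / (beta * beta * dispersion.n**2)
    np.clip(integrand, 0.0, None, out=integrand)
    total = FRANK_TAMM_PREFACTOR * float(np.trapezoid(integrand, dispersion.energy_ev))
    # rounding at the exact threshold velocity leaves O(1e-16) residuals
    return total if total > 1e-12 else 0.0


class CerenkovSampler:
    """Precomputed yield table and photon sampler for one dispersion curve.

    Caches dN/dl on a velocity grid so per-step evaluation is a single
    interpolation, and samples photon energies by rejection with the
    envelope at max(n) (exact for tabulated dispersion).
    """

    def __init__(self, dispersion: OpticalDispersion, n_beta: int = 512):
        self.dispersion = dispersion
        self.beta_threshold = 1.0 / dispersion.n_max
        self._beta_grid = np.linspace(self.beta_threshold, 1.0 - 1e-9, n_beta)
        self._yield_grid = np.array([yield_per_mm(b, dispersion) for b in self._beta_grid])
        self._e_min = dispersion.e_min
        self._e_span = dispersion.e_max - dispersion.e_min
        self._n_max = dispersion.n_max

    def yield_at(self, beta):
        """Interpolated dN/dl (photons/mm); zero below threshold."""
        return np.interp(beta, self._beta_grid, self._yield_grid, left=0.0, right=self._yield_grid[-1])

    def sample_energy(self, beta: float, rng: np.random.Generator) -> float | None:
        """One photon energy from the spectrum ~ (1 - 1/(beta^2 n^2(eps))).

        Returns None when the whole window is below threshold at this beta.
        """
        b2 = beta * beta
        env = 1.0 - 1.0 / (b2 * self._n_max * self._n_max)
        if env <= 0.0:
            return None
        for _ in range(10_000):
            e = self._e_min + self._e_span * rng.random()
            n_e = float(self.dispersion.refractive_index(e))
            f = 1.0 - 1.0 / (b2 * n_e * n_e)
            if f > 0.0 and rng.random() * env <= f:
                return e
        return None


def expected_photons(step: ElectronStep, dispersion: OpticalDispersion) -> float:
    """Expected Cerenkov count for a step: length x mean of endpoint yields.

    The pre/post average makes long steps that cross the emission threshold
    self-attenuate and keeps the expectation invariant under subdividing a
    step into smaller ones.
    """
    y1 = yield_per_mm(step.pre.beta, dispersion) if step.pre.beta > 0 else 0.0
    y2 = yield_per_mm(step.post.beta, dispersion) if step.post.beta > 0 else 0.0
    return step.length * 0.5 * (y1 + y2)


def _cone_direction(axis: np.ndarray, cos_theta: float, phi: float) -> np.ndarray:
    ax, ay, az = axis
    if abs(az) < 0.99:
        ux, uy, uz = -ay, ax, 0.0
    else:
        ux, uy, uz = 1.0, 0.0, 0.0
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = ay * uz - az * uy
    vy = az * ux - ax * uz
    vz = ax * uy - ay * ux
    sin_theta = math.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    cp, sp = math.cos(phi), math.sin(phi)
    d = np.array(
        [
            cos_theta * ax + sin_theta * (cp * ux + sp * vx),
            cos_theta * ay + sin_theta * (cp * uy + sp * vy),
            cos_theta * az + sin_theta * (cp * uz + sp * vz),
        ]
    )
    return d / np.linalg.norm(d)


def _emit_on_segment(
    sampler: CerenkovSampler,
    origin: np.ndarray,
    direction: np.ndarray,
    length: float,
    t0: float,
    dt: float,
    beta1: float,
    beta2: float,
    n_photons: int,
    mode: str,
    rng: np.random.Generator,
) -> list[OpticalPhoton]:
    """Place ``n_photons`` evenly along a rectilinear segment."""
    photons: list[OpticalPhoton] = []
    beta_bar = 0.5 * (beta1 + beta2)
    for _ in range(n_photons):
        u = rng.random()
        if mode == "local":
            beta_u = beta1 + u * (beta2 - beta1)
        elif mode == "mean-beta":
            beta_u = beta_bar
        else:  # pre
            beta_u = beta1
        if beta_u <= sampler.beta_threshold:
            continue  # locally sub-threshold: discard
        e = sampler.sample_energy(beta_u, rng)
        if e is None:
            continue
        n_e = float(sampler.dispersion.refractive_index(e))
        cos_theta = 1.0 / (beta_u * n_e)
        if cos_theta > 1.0:
            continue
        phi = rng.uniform(0.0, 2.0 * math.pi)
        photons.append(
            OpticalPhoton(
                origin=origin + u * length * direction,
                emission_time=t0 + u * dt,
                energy_ev=e,
                direction=_cone_direction(direction, cos_theta, phi),
                kind="cerenkov",
            )
        )
    return photons


def _expected_for_mode(sampler: CerenkovSampler, length: float, beta1: float, beta2: float, mode: str) -> float:
    if mode == "local":
        return length * 0.5 * float(sampler.yield_at(beta1) + sampler.yield_at(beta2))
    if mode == "mean-beta":
        return length * float(sampler.yield_at(0.5 * (beta1 + beta2)))
    if mode == "pre":
        return length * float(sampler.yield_at(beta1))
    raise ValueError(f"unknown yield mode {mode!r}")


def emit_cherenkov(
    step: ElectronStep,
    dispersion: OpticalDispersion,
    rng: np.random.Generator,
    mode: str = "local",
    sampler: CerenkovSampler | None = None,
) -> list[OpticalPhoton]:
    """Cerenkov photons of one electron step.

    Count ~ Poisson(expected), uniform placement along the step, emission
    time interpolated between the step endpoint times, energy sampled from
    the local Frank-Tamm spectrum, direction on the cone
    cos(theta) = 1/(beta*n(eps)) about the electron direction.
    """
    if sampler is None:
        sampler = CerenkovSampler(dispersion)
    mean = _expected_for_mode(sampler, step.length, step.pre.beta, step.post.beta, mode)
    if mean <= 0.0:
        return []
    n = int(rng.poisson(mean))
    if n == 0:
        return []
    dt = step.post.time - step.pre.time
    return _emit_on_segment(
        sampler,
        step.pre.position,
        step.pre.direction,
        step.length,
        step.pre.time,
        dt,
        step.pre.beta,
        step.post.beta,
        n,
        mode,
        rng,
    )


def emit_for_track(
    track: ElectronTrack,
    sampler: CerenkovSampler,
    rng: np.random.Generator,
    mode: str = "local",
) -> list[OpticalPhoton]:
    """Cerenkov photons of a whole track (vectorised per-step expectations)."""
    if track.n_steps == 0:
        return []
    y_pre = sampler.yield_at(track.pre_beta)
    y_post = sampler.yield_at(track.post_beta)
    if mode == "local":
        mean = track.length * 0.5 * (y_pre + y_post)
    elif mode == "mean-beta":
        mean = track.length * sampler.yield_at(0.5 * (track.pre_beta + track.post_beta))
    elif mode == "pre":
        mean = track.length * y_pre
    else:
        raise ValueError(f"unknown yield mode {mode!r}")
    counts = rng.poisson(mean)
    photons: list[OpticalPhoton] = []
    for i in np.nonzero(counts)[0]:
        dt = track.post_time[i] - track.pre_time[i]
        photons.extend(
            _emit_on_segment(
                sampler,
                track.pre_position[i],
                track.pre_direction[i],
                float(track.length[i]),
                float(track.pre_time[i]),
                float(dt),
                float(track.pre_beta[i]),
                float(track.post_beta[i]),
                int(counts[i]),
                mode,
                rng,
            )
        )
    return photons


def assign_orders(photons: list[OpticalPhoton]) -> list[OpticalPhoton]:
    """Sort photons of one event by emission time and number them from 1."""
    photons.sort(key=lambda p: p.emission_time)
    for i, p in enumerate(photons):
        p.order = i + 1
    return photons


# --- scintillation ----------------------------------------------------------

#: BGO steady-state light yield, photons/MeV.
BGO_LIGHT_YIELD_PER_MEV = 8200.0
#: BGO slow decay constant, ns (fast component and rise time excluded).
BGO_DECAY_NS = 300.0
#: Emission spectrum peak, nm, with a broad Gaussian width.
BGO_EMISSION_PEAK_NM = 480.0
BGO_EMISSION_SIGMA_NM = 55.0


def emit_scintillation(
    step: ElectronStep,
    rng: np.random.Generator,
    dispersion: OpticalDispersion,
    light_yield_per_mev: float = BGO_LIGHT_YIELD_PER_MEV,
    decimation: float = 100.0,
    decay_ns: float = BGO_DECAY_NS,
) -> list[OpticalPhoton]:
    """Scintillation photons of one step (isotropic, single exponential decay).

    The count is Poisson with mean dKE * yield / decimation; ``decimation``
    keeps the dominant scintillation light from swamping Cerenkov-focused
    studies and is an analysis-time scaling, not physics.  Photon energies
    are drawn from a Gaussian emission spectrum peaked at 480 nm, truncated
    to the optical window.
    """
    if decimation < 1:
        raise ValueError("decimation must be >= 1")
    dke = step.pre.ke - step.post.ke
    if dke <= 0.0:
        return []
    mean = dke * light_yield_per_mev / decimation
    n = int(rng.poisson(mean))
    photons: list[OpticalPhoton] = []
    dt = step.post.time - step.pre.time
    e_lo, e_hi = dispersion.e_min, dispersion.e_max
    for _ in range(n):
        u = rng.random()
        # wavelength-Gaussian spectrum, rejection into the window
        for _ in range(1000):
            lam = rng.normal(BGO_EMISSION_PEAK_NM, BGO_EMISSION_SIGMA_NM)
            if lam > 0:
                e = wavelength_nm_to_ev(lam)
                if e_lo <= e <= e_hi:
                    break
        else:
            e = 0.5 * (e_lo + e_hi)
        cos_t = rng.uniform(-1.0, 1.0)
        sin_t = math.sqrt(1.0 - cos_t * cos_t)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        photons.append(
            OpticalPhoton(
                origin=step.pre.position + u * step.length * step.pre.direction,
                emission_time=step.pre.time + u * dt + rng.exponential(decay_ns),
                energy_ev=float(e),
                direction=np.array([sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t]),
                kind="scintillation",
            )
        )
    return photons
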