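"""Photoelectric recoil-electron generation and stepwise transport.

The recoil electron from a photoelectric interaction is tracked step by
step.  Each step length is the minimum of two limits:

* the range-based default step: while the electron is above the Cerenkov
  threshold, the step is capped at range(KE) - range(KE_threshold), so a
  single step never carries the electron through the threshold; below
  threshold the electron takes its full remaining range in one step
  (the final-range rule for ranges well below a millimetre);
* the velocity-change limit: when a maximum fractional velocity change
  per step (delta_beta) is imposed, the step shrinks to
  dl = m * dgamma / (dE/dx) with dgamma evaluated for beta_f = beta*(1-delta_beta).

Between steps the direction is deflected by a Highland/Gaussian
multiple-scattering angle; motion within a step is rectilinear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import C_VACUUM_MM_NS, ELECTRON_MASS_MEV
from .materials import Material, cherenkov_threshold
from .stopping import LossTables

__all__ = [
    "ElectronState",
    "ElectronStep",
    "ElectronTrack",
    "kinematics",
    "sample_interaction_depth",
    "sample_sauter_cosine",
    "make_photoelectron",
    "limited_step_length",
    "scatter_direction",
    "propagate_electron",
]

#: Tracking cutoff: electrons at or below this kinetic energy are stopped.
#: Far below the ~53 keV Cerenkov threshold, so photon physics is unaffected.
KE_CUTOFF_MEV = 1e-3


def kinematics(ke: float) -> tuple[float, float]:
    """Relativistic velocity and Lorentz factor (beta, gamma) at ``ke`` MeV."""
    if ke < 0:
        raise ValueError("kinetic energy must be non-negative")
    gamma = 1.0 + ke / ELECTRON_MASS_MEV
    beta = math.sqrt(max(0.0, 1.0 - 1.0 / (gamma * gamma)))
    return beta, gamma


@dataclass
class ElectronState:
    """Kinematic state of the electron at a step boundary."""

    position: np.ndarray  # mm
    direction: np.ndarray  # unit vector
    ke: float  # MeV
    beta: float
    gamma: float
    time: float  # ns

    @classmethod
    def from_ke(cls, position, direction, ke: float, time: float = 0.0) -> "ElectronState":
        direction = np.asarray(direction, dtype=float)
        norm = float(np.linalg.norm(direction))
        if abs(norm - 1.0) > 1e-9:
            direction = direction / norm
        beta, gamma = kinematics(ke)
        return cls(np.asarray(position, dtype=float), direction, ke, beta, gamma, time)


@dataclass
class ElectronStep:
    """One rectilinear step with its pre/post states."""

    pre: ElectronState
    post: ElectronState
    length: float  # mm

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("step length must be positive")


@dataclass
class ElectronTrack:
    """One electron track as contiguous arrays (one row per step).

    Post-step quantities of step i equal the pre-step quantities of step
    i+1; the last post state is ``final_state``.  ``steps`` materialises
    :class:`ElectronStep` objects on demand.
    """

    parent_event_id: int
    pre_ke: np.ndarray
    pre_beta: np.ndarray
    pre_time: np.ndarray
    pre_position: np.ndarray  # (n, 3)
    pre_direction: np.ndarray  # (n, 3)
    length: np.ndarray
    post_ke: np.ndarray
    post_beta: np.ndarray
    post_time: np.ndarray
    final_state: ElectronState = field(repr=False, default=None)

    @property
    def n_steps(self) -> int:
        return len(self.length)

    @property
    def track_length_mm(self) -> float:
        return float(self.length.sum())

    @property
    def mean_step_length_mm(self) -> float:
        return float(self.length.mean())

    def post_position(self, i: int) -> np.ndarray:
        return self.pre_position[i] + self.length[i] * self.pre_direction[i]

    @property
    def steps(self) -> list[ElectronStep]:
        out = []
        for i in range(self.n_steps):
            pre = ElectronState(
                self.pre_position[i].copy(),
                self.pre_direction[i].copy(),
                float(self.pre_ke[i]),
                float(self.pre_beta[i]),
                1.0 + float(self.pre_ke[i]) / ELECTRON_MASS_MEV,
                float(self.pre_time[i]),
            )
            if i + 1 < self.n_steps:
                post_dir = self.pre_direction[i + 1].copy()
            else:
                post_dir = self.final_state.direction.copy()
            post = ElectronState(
                self.post_position(i),
                post_dir,
                float(self.post_ke[i]),
                float(self.post_beta[i]),
                1.0 + float(self.post_ke[i]) / ELECTRON_MASS_MEV,
                float(self.post_time[i]),
            )
            out.append(ElectronStep(pre, post, float(self.length[i])))
        return out


def sample_interaction_depth(mu: float, rng: np.random.Generator, max_depth: float = 20.0) -> float:
    """Exponential interaction depth, resampled until it falls inside the crystal.

    Only gammas that interact photoelectrically inside the crystal are kept,
    so the depth distribution is the exponential truncated at the crystal
    length (default 20 mm).
    """
    if mu <= 0:
        raise ValueError("attenuation coefficient must be positive")
    while True:
        d = rng.exponential(1.0 / mu)
        if d <= max_depth:
            return d


def sample_sauter_cosine(beta: float, rng: np.random.Generator) -> float:
    """Polar cosine of the photoelectron w.r.t. the gamma axis.

    Sauter distribution f(theta) ~ sin^2(theta) / (1 - beta*cos(theta))^4,
    sampled by rejection with a uniform proposal in cos(theta).  The mode is
    at cos* = (-1 + sqrt(1 + 8 beta^2)) / (2 beta), tilting emission forward
    for relativistic electrons.
    """
    if beta <= 0.0:
        # non-relativistic limit: pure sin^2 distribution
        while True:
            c = rng.uniform(-1.0, 1.0)
            if rng.random() <= 1.0 - c * c:
                return c
    c_star = (-1.0 + math.sqrt(1.0 + 8.0 * beta * beta)) / (2.0 * beta)
    f_max = (1.0 - c_star * c_star) / (1.0 - beta * c_star) ** 4
    while True:
        c = rng.uniform(-1.0, 1.0)
        f = (1.0 - c * c) / (1.0 - beta * c) ** 4
        if rng.random() * f_max <= f:
            return c


def make_photoelectron(
    e_gamma: float,
    mat: Material,
    rng: np.random.Generator,
    depth: float = 0.0,
    source_distance: float = 10.0,
    event_id: int = 0,
) -> ElectronState:
    """Recoil electron from a photoelectric interaction of a gamma along +z.

    The shell is chosen by the configured selection probabilities, the
    kinetic energy is E_gamma minus the binding energy, and the direction is
    drawn from the Sauter distribution about the gamma axis.  The start time
    is the gamma flight time from the source to the interaction point.
    """
    if e_gamma <= mat.max_binding_mev:
        raise ValueError("gamma energy must exceed the largest shell binding energy")
    u = rng.random()
    acc = 0.0
    shell = mat.shells[-1]
    for s in mat.shells:
        acc += s.probability
        if u <= acc:
            shell = s
            break
    ke = e_gamma - shell.binding_mev
    beta, gamma = kinematics(ke)
    cos_t = sample_sauter_cosine(beta, rng)
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    direction = np.array([sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t])
    position = np.array([0.0, 0.0, depth])
    time = (source_distance + depth) / C_VACUUM_MM_NS
    return ElectronState(position, direction, ke, beta, gamma, time)


def _default_step(ke: float, tables: LossTables, cerenkov_ke_min: float | None) -> float:
    """Range-based default step length at kinetic energy ``ke``."""
    r = tables.range_at(ke)
    if cerenkov_ke_min is not None and ke > cerenkov_ke_min:
        return r - tables.range_at(cerenkov_ke_min)
    return r


def limited_step_length(
    state: ElectronState,
    delta_beta: float | None,
    tables: LossTables,
    cerenkov_ke_min: float | None = None,
) -> float:
    """Step length under the velocity-change limit.

    With ``delta_beta`` set (a fraction in (0, 1]) and the electron above the
    Cerenkov threshold, dl = m * dgamma / (dE/dx) where dgamma follows from
    beta_f = beta*(1 - delta_beta); the step is the minimum of dl and the
    range-based default step.  With ``delta_beta`` None (unlimited) or below
    threshold, the default step is returned unchanged.
    """
    if delta_beta is not None and not (0.0 < delta_beta <= 1.0):
        raise ValueError("delta_beta must lie in (0, 1] or be None")
    dx = _default_step(state.ke, tables, cerenkov_ke_min)
    above = cerenkov_ke_min is None or state.ke > cerenkov_ke_min
    if delta_beta is None or not above:
        return dx
    beta_f = state.beta * (1.0 - delta_beta)
    dgamma = state.gamma - 1.0 / math.sqrt(1.0 - beta_f * beta_f)
    dl = ELECTRON_MASS_MEV * dgamma / tables.dedx_at(state.ke)
    return min(dl, dx)


def highland_theta0(ke: float, beta: float, step_mm: float, x0_mm: float) -> float:
    """Highland multiple-scattering width (rad) for a path ``step_mm``."""
    if step_mm <= 0.0:
        return 0.0
    pc = math.sqrt(ke * (ke + 2.0 * ELECTRON_MASS_MEV))  # MeV
    x_ratio = step_mm / x0_mm
    corr = 1.0 + 0.038 * math.log(x_ratio)
    corr = max(corr, 0.1)
    return 13.6 / (beta * pc) * math.sqrt(x_ratio) * corr


def _rotate_scalar(dx: float, dy: float, dz: float, theta: float, phi: float):
    """Scalar core of :func:`_rotate_about`."""
    # orthonormal basis perpendicular to direction
    if abs(dz) < 0.99:
        ux, uy, uz = -dy, dx, 0.0
    else:
        ux, uy, uz = 1.0, 0.0, 0.0
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    st, ct = math.sin(theta), math.cos(theta)
    cp, sp = math.cos(phi), math.sin(phi)
    nx = ct * dx + st * (cp * ux + sp * vx)
    ny = ct * dy + st * (cp * uy + sp * vy)
    nz = ct * dz + st * (cp * uz + sp * vz)
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


def _rotate_about(direction: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Rotate ``direction`` by polar angle theta (azimuth phi) about itself."""
    dx, dy, dz = (float(v) for v in direction)
    return np.array(_rotate_scalar(dx, dy, dz, theta, phi))


def scatter_direction(
    state: ElectronState,
    step_length: float,
    mat: Material,
    rng: np.random.Generator,
) -> np.ndarray:
    """New direction after multiple scattering over ``step_length`` mm.

    Polar deflection drawn from a Gaussian of Highland width (clamped at pi),
    azimuth uniform.
    """
    if step_length <= 0:
        raise ValueError("step length must be positive")
    theta0 = highland_theta0(state.ke, state.beta, step_length, mat.radiation_length_mm)
    theta = abs(rng.normal(0.0, theta0)) if theta0 > 0 else 0.0
    theta = min(theta, math.pi)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return _rotate_about(state.direction, theta, phi)


def propagate_electron(
    initial: ElectronState,
    delta_beta: float | None,
    tables: LossTables,
    mat: Material,
    rng: np.random.Generator,
    ke_cutoff: float = KE_CUTOFF_MEV,
    event_id: int = 0,
    max_steps: int = 2_000_000,
) -> ElectronTrack:
    """Track the electron until its kinetic energy reaches the cutoff.

    Loop: compute the limited step length, move rectilinearly, deplete the
    kinetic energy through the range table, advance the clock with the
    pre-step velocity, deflect the direction, record the step.

    The inner loop runs in scalar arithmetic with local interpolation on the
    loss tables (a small-step track has thousands of steps per event).
    """
    if initial.ke <= ke_cutoff:
        raise ValueError("initial kinetic energy must exceed the tracking cutoff")
    _, ke_thresh = cherenkov_threshold(mat.dispersion)

    # local copies of the tables for fast scalar interpolation
    log_ke = tables._log_ke
    dedx_arr = tables.dedx
    range_arr = tables.csda_range
    ke_lo = tables.ke_min
    m = ELECTRON_MASS_MEV
    x0 = mat.radiation_length_mm
    interp = np.interp
    log = math.log
    sqrt = math.sqrt

    pre_ke, pre_beta, pre_time, length = [], [], [], []
    pre_pos, pre_dir = [], []
    post_ke_l, post_beta_l, post_time_l = [], [], []

    x, y, z = (float(v) for v in initial.position)
    dx, dy, dz = (float(v) for v in initial.direction)
    ke, beta, gamma, t = initial.ke, initial.beta, initial.gamma, initial.time
    range_th = float(interp(log(ke_thresh), log_ke, range_arr))

    for _ in range(max_steps):
        lke = log(ke)
        remaining = float(interp(lke, log_ke, range_arr))
        if ke > ke_thresh:
            step = remaining - range_th
            if delta_beta is not None:
                beta_f = beta * (1.0 - delta_beta)
                dgamma = gamma - 1.0 / sqrt(1.0 - beta_f * beta_f)
                dl = m * dgamma / float(interp(lke, log_ke, dedx_arr))
                if dl < step:
                    step = dl
        else:
            step = remaining
        if step > remaining:
            step = remaining
        if step <= 0.0:
            break
        r_new = remaining - step
        if r_new <= range_arr[0]:
            new_ke = ke_lo
        else:
            new_ke = math.exp(float(interp(r_new, range_arr, log_ke)))
        new_gamma = 1.0 + new_ke / m
        new_beta = sqrt(max(0.0, 1.0 - 1.0 / (new_gamma * new_gamma)))
        new_time = t + step / (beta * C_VACUUM_MM_NS)

        pre_ke.append(ke)
        pre_beta.append(beta)
        pre_time.append(t)
        pre_pos.append((x, y, z))
        pre_dir.append((dx, dy, dz))
        length.append(step)
        post_ke_l.append(new_ke)
        post_beta_l.append(new_beta)
        post_time_l.append(new_time)

        x += step * dx
        y += step * dy
        z += step * dz
        # multiple-scattering deflection (Highland), applied at the step end
        theta0 = highland_theta0(ke, beta, step, x0)
        if theta0 > 0.0:
            theta = abs(rng.normal(0.0, theta0))
            if theta > math.pi:
                theta = math.pi
            phi = rng.uniform(0.0, 2.0 * math.pi)
            dx, dy, dz = _rotate_scalar(dx, dy, dz, theta, phi)
        ke, beta, gamma, t = new_ke, new_beta, new_gamma, new_time
        if ke <= ke_cutoff:
            break

    final = ElectronState(
        np.array([x, y, z]), np.array([dx, dy, dz]), ke, beta, gamma, t
    )
    return ElectronTrack(
        parent_event_id=event_id,
        pre_ke=np.asarray(pre_ke),
        pre_beta=np.asarray(pre_beta),
        pre_time=np.asarray(pre_time),
        pre_position=np.asarray(pre_pos),
        pre_direction=np.asarray(pre_dir),
        length=np.asarray(length),
        post_ke=np.asarray(post_ke_l),
        post_beta=np.asarray(post_beta_l),
        post_time=np.asarray(post_time_l),
        final_state=final,
    )
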