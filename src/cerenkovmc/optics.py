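"""Optical photon transport in a wrapped box crystal with a front detector.

The crystal is a rectangular box (default 3 x 3 x 20 mm).  Five faces are
polished and wrapped in Teflon; the sixth face (z = 0, towards the gamma
source: "front arrangement") is polished and coupled through optical
grease (n = 1.5) to an ideal photodetector (detection efficiency 1).

Surface model: analytic unpolarised Fresnel at every face.  A polished
surface is not an ideal plane -- its micro-facet normals scatter with an
RMS tilt of about 1.3 degrees -- so each interaction draws a facet normal
with a small Gaussian tilt before evaluating Fresnel.  Wrapped faces carry
an *effective* per-interaction reflectivity (default 0.98, the measured
scale for Teflon-wrapped polished crystals): at every wrapped-face
interaction, including total internal reflection, the photon survives with
that probability, matching the empirical fact that real wrapped surfaces
lose a percent-level fraction per bounce at all angles.  Surviving photons
reflect specularly off the facet when Fresnel says so, otherwise they reach
the Teflon and re-enter diffusely (Lambertian).  Light transmitted through
the detector face is detected.

Photons propagate at the group velocity c/n_g(eps); bulk absorption is
exponential with the dispersion table's absorption length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import C_VACUUM_MM_NS
from .materials import OpticalDispersion
from .cerenkov import OpticalPhoton

__all__ = [
    "CrystalGeometry",
    "DetectedPhoton",
    "TraceResult",
    "fresnel_reflectance",
    "fresnel_interaction",
    "photon_speed",
    "trace",
]


@dataclass
class CrystalGeometry:
    """Box crystal with five wrapped faces and one detector-coupled face (z=0)."""

    half_x: float = 1.5  # mm
    half_y: float = 1.5  # mm
    length: float = 20.0  # mm, crystal occupies z in [0, length]
    wrap_reflectivity: float = 0.98
    grease_index: float = 1.5
    facet_sigma_deg: float = 1.3  # polished-surface micro-facet RMS tilt
    max_reflections: int = 1000

    def __post_init__(self) -> None:
        if min(self.half_x, self.half_y, self.length) <= 0:
            raise ValueError("geometry dimensions must be positive")
        if not (0.0 <= self.wrap_reflectivity <= 1.0):
            raise ValueError("wrap reflectivity must lie in [0, 1]")

    def contains(self, p) -> bool:
        x, y, z = p
        return (
            -self.half_x - 1e-9 <= x <= self.half_x + 1e-9
            and -self.half_y - 1e-9 <= y <= self.half_y + 1e-9
            and -1e-9 <= z <= self.length + 1e-9
        )


@dataclass
class DetectedPhoton:
    """A photon that crossed into the detector coupling."""

    detection_time: float  # ns, emission time + transit
    transit_time: float  # ns
    path_length: float  # mm inside the crystal
    kind: str
    order: int
    n_reflections: int
    energy_ev: float = 0.0


@dataclass
class TraceResult:
    """Outcome of tracing one photon: detected or lost with a reason."""

    status: str  # "detected" | "absorbed" | "wrap" | "trapped"
    detected: DetectedPhoton | None = None
    path_length: float = 0.0
    n_reflections: int = 0


def fresnel_reflectance(cos_i: float, n1: float, n2: float) -> float:
    """Unpolarised Fresnel reflectance for incidence cosine ``cos_i``.

    Returns 1 beyond the total-internal-reflection angle (sin_i > n2/n1).
    """
    cos_i = abs(cos_i)
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) ** 2 * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


def fresnel_interaction(
    direction: np.ndarray,
    face_normal: np.ndarray,
    n1: float,
    n2: float,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray]:
    """Reflect or refract at a planar interface (outward normal ``face_normal``).

    With probability R(theta_i) the photon reflects specularly, otherwise it
    refracts by Snell's law; total internal reflection always reflects.
    Index-matched interfaces transmit with the direction unchanged.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(face_normal, dtype=float)
    cos_i = float(np.dot(d, n))
    if n1 == n2:
        return "transmitted", d
    r = fresnel_reflectance(cos_i, n1, n2)
    if rng.random() < r:
        return "reflected", d - 2.0 * cos_i * n
    eta = n1 / n2
    sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
    cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
    t = eta * d + (cos_t - eta * abs(cos_i)) * math.copysign(1.0, cos_i) * n
    return "transmitted", t / np.linalg.norm(t)


def photon_speed(dispersion: OpticalDispersion, energy_ev: float, mode: str = "group") -> float:
    """Propagation speed (mm/ns): c over the group (default) or phase index."""
    if mode == "group":
        n = float(dispersion.group_index(energy_ev))
    elif mode == "phase":
        n = float(dispersion.refractive_index(energy_ev))
    else:
        raise ValueError("speed mode must be 'group' or 'phase'")
    return C_VACUUM_MM_NS / n


def _facet_normal(nx: float, ny: float, nz: float, sigma: float, rng) -> tuple[float, float, float]:
    """Outward facet normal with Gaussian micro-tilt about the face normal."""
    if sigma <= 0.0:
        return nx, ny, nz
    # tangential perturbation; exact tangent frame is irrelevant for axis-aligned faces
    tx = rng.normal(0.0, sigma)
    ty = rng.normal(0.0, sigma)
    if nz != 0.0:
        fx, fy, fz = tx, ty, nz * math.sqrt(max(1e-12, 1.0 - tx * tx - ty * ty))
    elif nx != 0.0:
        fx, fy, fz = nx * math.sqrt(max(1e-12, 1.0 - tx * tx - ty * ty)), tx, ty
    else:
        fx, fy, fz = tx, ny * math.sqrt(max(1e-12, 1.0 - tx * tx - ty * ty)), ty
    norm = math.sqrt(fx * fx + fy * fy + fz * fz)
    return fx / norm, fy / norm, fz / norm


def _lambertian(inward: tuple[float, float, float], rng) -> tuple[float, float, float]:
    """Cosine-weighted direction about the inward face normal."""
    u1, u2 = rng.random(), rng.random()
    ct = math.sqrt(u1)
    st = math.sqrt(1.0 - u1)
    phi = 2.0 * math.pi * u2
    lx, ly = st * math.cos(phi), st * math.sin(phi)
    ix, iy, iz = inward
    # build tangent frame
    if abs(iz) < 0.99:
        ux, uy, uz = -iy, ix, 0.0
    else:
        ux, uy, uz = 1.0, 0.0, 0.0
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = iy * uz - iz * uy
    vy = iz * ux - ix * uz
    vz = ix * uy - iy * ux
    dx = lx * ux + ly * vx + ct * ix
    dy = lx * uy + ly * vy + ct * iy
    dz = lx * uz + ly * vz + ct * iz
    norm = math.sqrt(dx * dx + dy * dy + dz * dz)
    return dx / norm, dy / norm, dz / norm


def trace(
    photon: OpticalPhoton,
    geom: CrystalGeometry,
    dispersion: OpticalDispersion,
    rng: np.random.Generator,
    speed_mode: str = "group",
) -> TraceResult:
    """Trace one photon to detection or loss.

    Iterates: advance to the nearest face, test bulk absorption over the
    segment, then resolve the surface interaction (Fresnel against air at
    wrapped faces with Lambertian Teflon re-entry, Fresnel against grease at
    the detector face).  Photons exceeding ``max_reflections`` are trapped.
    """
    x, y, z = (float(v) for v in photon.origin)
    if not geom.contains((x, y, z)):
        raise ValueError("photon origin lies outside the crystal")
    dx, dy, dz = (float(v) for v in photon.direction)

    n_phase = float(dispersion.refractive_index(photon.energy_ev))
    abs_len = float(dispersion.absorption_length(photon.energy_ev))
    speed = photon_speed(dispersion, photon.energy_ev, mode=speed_mode)
    sigma = math.radians(geom.facet_sigma_deg)
    hx, hy, lz = geom.half_x, geom.half_y, geom.length
    n_grease = geom.grease_index
    eps = 1e-12

    path = 0.0
    refl = 0
    rand = rng.random
    exp = math.exp

    while refl <= geom.max_reflections:
        # distance to each face along the current direction
        t_min = math.inf
        face = -1  # 0:+x 1:-x 2:+y 3:-y 4:+z(back) 5:-z(detector)
        if dx > eps:
            t = (hx - x) / dx
            if t < t_min:
                t_min, face = t, 0
        elif dx < -eps:
            t = (-hx - x) / dx
            if t < t_min:
                t_min, face = t, 1
        if dy > eps:
            t = (hy - y) / dy
            if t < t_min:
                t_min, face = t, 2
        elif dy < -eps:
            t = (-hy - y) / dy
            if t < t_min:
                t_min, face = t, 3
        if dz > eps:
            t = (lz - z) / dz
            if t < t_min:
                t_min, face = t, 4
        elif dz < -eps:
            t = (0.0 - z) / dz
            if t < t_min:
                t_min, face = t, 5
        if face < 0 or not math.isfinite(t_min):
            return TraceResult("trapped", None, path, refl)
        t_min = max(t_min, 0.0)

        # bulk absorption over the segment
        if rand() > exp(-t_min / abs_len):
            return TraceResult("absorbed", None, path + t_min * rand(), refl)

        x += t_min * dx
        y += t_min * dy
        z += t_min * dz
        path += t_min

        if face == 0:
            no = (1.0, 0.0, 0.0)
            x = hx
        elif face == 1:
            no = (-1.0, 0.0, 0.0)
            x = -hx
        elif face == 2:
            no = (0.0, 1.0, 0.0)
            y = hy
        elif face == 3:
            no = (0.0, -1.0, 0.0)
            y = -hy
        elif face == 4:
            no = (0.0, 0.0, 1.0)
            z = lz
        else:
            no = (0.0, 0.0, -1.0)
            z = 0.0

        n2 = n_grease if face == 5 else 1.0

        # effective surface loss at wrapped faces (all angles, TIR included)
        if face != 5 and rand() >= geom.wrap_reflectivity:
            return TraceResult("wrap", None, path, refl)

        # micro-facet normal; require it to face the incoming photon
        for _ in range(8):
            fnx, fny, fnz = _facet_normal(no[0], no[1], no[2], sigma, rng)
            cos_i = dx * fnx + dy * fny + dz * fnz
            if cos_i > 0.0:
                break
        else:
            fnx, fny, fnz = no
            cos_i = dx * fnx + dy * fny + dz * fnz

        r = fresnel_reflectance(cos_i, n_phase, n2)
        if rand() < r:
            # specular reflection off the facet; keep the photon inside
            rx = dx - 2.0 * cos_i * fnx
            ry = dy - 2.0 * cos_i * fny
            rz = dz - 2.0 * cos_i * fnz
            if rx * no[0] + ry * no[1] + rz * no[2] >= 0.0:
                # facet tilt would send it outward: fall back to the mean plane
                cos_p = dx * no[0] + dy * no[1] + dz * no[2]
                rx = dx - 2.0 * cos_p * no[0]
                ry = dy - 2.0 * cos_p * no[1]
                rz = dz - 2.0 * cos_p * no[2]
            dx, dy, dz = rx, ry, rz
            refl += 1
            continue

        if face == 5:
            # transmitted into the grease: detected (ideal photodetector)
            transit = path / speed
            det = DetectedPhoton(
                detection_time=photon.emission_time + transit,
                transit_time=transit,
                path_length=path,
                kind=photon.kind,
                order=photon.order,
                n_reflections=refl,
                energy_ev=photon.energy_ev,
            )
            return TraceResult("detected", det, path, refl)

        # transmitted through a wrapped face: diffuse Teflon re-entry
        inward = (-no[0], -no[1], -no[2])
        dx, dy, dz = _lambertian(inward, rng)
        refl += 1
        continue

    return TraceResult("trapped", None, path, refl)
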