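"""Fresnel optics and photon ray tracing through the wrapped crystal."""

import math

import numpy as np
import pytest

import cerenkovmc as c
from cerenkovmc.optics import fresnel_reflectance


def _photon(origin, direction, energy_ev=2.5, t0=0.0):
    d = np.asarray(direction, float)
    return c.OpticalPhoton(
        origin=np.asarray(origin, float),
        emission_time=t0,
        energy_ev=energy_ev,
        direction=d / np.linalg.norm(d),
        kind="cerenkov",
        order=1,
    )


def test_fresnel_reflectance_values():
    # normal incidence closed form ((n1-n2)/(n1+n2))^2
    assert fresnel_reflectance(1.0, 2.15, 1.0) == pytest.approx(0.1333, abs=2e-4)
    # index matching: no reflection
    assert fresnel_reflectance(0.7, 1.5, 1.5) == 0.0
    # total internal reflection beyond the critical angle
    crit = math.asin(1.0 / 2.15)
    assert fresnel_reflectance(math.cos(crit * 1.05), 2.15, 1.0) == 1.0
    assert 0.0 < fresnel_reflectance(math.cos(crit * 0.9), 2.15, 1.0) < 1.0


def test_fresnel_interaction_branches(rng):
    normal = np.array([0.0, 0.0, 1.0])
    # index-matched: transmitted, direction unchanged
    d = np.array([0.3, 0.0, math.sqrt(1 - 0.09)])
    kind, out = c.fresnel_interaction(d, normal, 1.5, 1.5, rng)
    assert kind == "transmitted"
    np.testing.assert_allclose(out, d)
    # beyond critical angle: always reflected, specular
    grazing = np.array([0.95, 0.0, math.sqrt(1 - 0.95**2)])
    for _ in range(50):
        kind, out = c.fresnel_interaction(grazing, normal, 2.15, 1.0, rng)
        assert kind == "reflected"
        np.testing.assert_allclose(out, [0.95, 0.0, -grazing[2]], atol=1e-12)
    # transmitted rays obey Snell's law
    n1, n2 = 2.15, 1.5
    incoming = np.array([0.4, 0.0, math.sqrt(1 - 0.16)])
    for _ in range(200):
        kind, out = c.fresnel_interaction(incoming, normal, n1, n2, rng)
        if kind == "transmitted":
            sin_t = math.sqrt(out[0] ** 2 + out[1] ** 2)
            assert sin_t == pytest.approx(n1 / n2 * 0.4, abs=1e-9)
            break
    else:
        pytest.fail("no transmission in 200 trials at moderate incidence")


def test_photon_speed(bgo):
    flat = c.OpticalDispersion(np.array([1.5, 3.5]), np.array([2.15, 2.15]), np.array([3e3, 3e3]))
    assert c.photon_speed(flat, 2.5) == pytest.approx(299.792458 / 2.15, rel=1e-9)
    near_vacuum = c.OpticalDispersion(
        np.array([1.5, 3.5]), np.array([1.0 + 1e-9, 1.0 + 1e-9]), np.array([3e3, 3e3])
    )
    assert c.photon_speed(near_vacuum, 2.0) == pytest.approx(299.79, abs=0.01)
    # group speed is slower than phase speed under normal dispersion
    mid = 0.5 * (bgo.dispersion.e_min + bgo.dispersion.e_max)
    assert c.photon_speed(bgo.dispersion, mid, "group") < c.photon_speed(bgo.dispersion, mid, "phase")


@pytest.fixture(scope="module")
def geom():
    return c.CrystalGeometry()


def test_direct_hit_path_and_time(geom, bgo, rng):
    """A photon aimed straight at the detector face crosses exactly 10 mm."""
    detected = []
    for _ in range(100):
        r = c.trace(_photon([0, 0, 10.0], [0, 0, -1]), geom, bgo.dispersion, rng)
        if r.status == "detected":
            detected.append(r.detected)
    assert detected  # transmission probability at near-normal incidence is high
    for d in detected:
        if d.n_reflections == 0:
            assert d.path_length == pytest.approx(10.0, abs=1e-9)
            speed = c.photon_speed(bgo.dispersion, 2.5)
            assert d.transit_time == pytest.approx(10.0 / speed, rel=1e-9)
            assert d.detection_time == pytest.approx(d.transit_time)


def test_forward_photon_needs_back_reflection(geom, bgo, rng):
    """A forward photon from z=10 travels >= 30 mm before detection."""
    for _ in range(300):
        r = c.trace(_photon([0, 0, 10.0], [0, 0, 1]), geom, bgo.dispersion, rng)
        if r.status == "detected":
            assert r.detected.path_length >= 30.0 - 1e-6
            assert r.detected.n_reflections >= 1


def test_tir_trapped_directions(bgo, rng):
    """Directions beyond the TIR angle at every face are never detected."""
    geom = c.CrystalGeometry(wrap_reflectivity=1.0, facet_sigma_deg=0.0)
    # |dx|, |dy| below cos(27.7 deg) = 0.885 (TIR against air at the wrapped
    # faces) and |dz| below cos(44.3 deg) = 0.716 (TIR against the grease)
    d = np.array([0.6, 0.45, 0.66])
    d /= np.linalg.norm(d)
    r = c.trace(_photon([0, 0, 1.0], d), geom, bgo.dispersion, rng)
    assert r.status in ("trapped", "absorbed")
    assert r.n_reflections > 50 or r.status == "absorbed"


def test_origin_outside_crystal_rejected(geom, bgo, rng):
    with pytest.raises(ValueError):
        c.trace(_photon([0, 0, 25.0], [0, 0, -1]), geom, bgo.dispersion, rng)


def test_flux_audit(geom, bgo, bgo_tables, bgo_sampler, rng):
    """Every emitted photon is detected or lost with a recorded reason."""
    summary, raw = c.run_single(
        c.make_bgo(), None, 30, seed=99, tables=bgo_tables, sampler=bgo_sampler,
        optical_transport=True, yield_mode="mean-beta",
    )
    total = summary.n_detected + sum(summary.loss_counts.values())
    assert total == summary.n_emitted


def test_detection_time_tracks_path_length(geom, bgo, rng):
    """Transit time is exactly path/speed, so time orders with path."""
    results = []
    for i in range(400):
        cos_t = rng.uniform(-1, 1)
        sin_t = math.sqrt(1 - cos_t**2)
        phi = rng.uniform(0, 2 * math.pi)
        p = _photon([0, 0, 8.0], [sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t])
        r = c.trace(p, geom, bgo.dispersion, rng)
        if r.status == "detected":
            results.append(r.detected)
    assert len(results) > 20
    speed = c.photon_speed(bgo.dispersion, 2.5)
    for d in results:
        assert d.transit_time == pytest.approx(d.path_length / speed, rel=1e-9)
    paths = np.array([d.path_length for d in results])
    times = np.array([d.transit_time for d in results])
    assert np.corrcoef(paths, times)[0, 1] > 0.999
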