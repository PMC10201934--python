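"""Frank-Tamm yield integration and per-step photon generation."""

import math

import numpy as np
import pytest

import cerenkovmc as c
from cerenkovmc.transport import ElectronState


def _step_from_tables(tables, ke_pre, length, direction=(0, 0, 1), origin=(0, 0, 5.0)):
    pre = ElectronState.from_ke(origin, direction, ke_pre)
    ke_post = tables.ke_after_path(ke_pre, length)
    post = ElectronState.from_ke(
        np.asarray(origin, float) + length * np.asarray(direction, float),
        direction,
        ke_post,
        time=length / (pre.beta * c.C_VACUUM_MM_NS),
    )
    return c.ElectronStep(pre, post, length)


def test_yield_matches_constant_n_closed_form():
    """Numeric Frank-Tamm integral equals the constant-n closed form to 1e-10."""
    d = c.OpticalDispersion(
        np.array([1.5498, 3.8745]), np.array([2.15, 2.15]), np.array([3e3, 3e3])
    )
    beta = 0.835906
    closed = c.FRANK_TAMM_PREFACTOR * (3.8745 - 1.5498) * (1.0 - 1.0 / (beta**2 * 2.15**2))
    assert c.yield_per_mm(beta, d) == pytest.approx(closed, rel=1e-10)
    assert closed == pytest.approx(59.35, abs=0.01)


def test_yield_zero_below_threshold(bgo):
    beta_t, _ = c.cherenkov_threshold(bgo.dispersion)
    assert c.yield_per_mm(beta_t, bgo.dispersion) == 0.0
    assert c.yield_per_mm(0.5 * beta_t, bgo.dispersion) == 0.0


def test_yield_monotone_in_beta(bgo):
    betas = np.linspace(0.45, 0.999, 30)
    ys = [c.yield_per_mm(b, bgo.dispersion) for b in betas]
    assert all(a < b for a, b in zip(ys, ys[1:]))


def test_expected_photons_subdivision_invariance(bgo, bgo_tables):
    """Splitting a fine step conserves the expected count within 0.5%."""
    whole = _step_from_tables(bgo_tables, 0.42, 0.004)
    first = _step_from_tables(bgo_tables, 0.42, 0.002)
    second = _step_from_tables(bgo_tables, first.post.ke, 0.002)
    total_split = c.expected_photons(first, bgo.dispersion) + c.expected_photons(
        second, bgo.dispersion
    )
    assert total_split == pytest.approx(c.expected_photons(whole, bgo.dispersion), rel=5e-3)


def test_expected_photons_zero_when_subthreshold(bgo, bgo_tables):
    step = _step_from_tables(bgo_tables, 0.02, 1e-4)
    assert c.expected_photons(step, bgo.dispersion) == 0.0
    assert c.emit_cherenkov(step, bgo.dispersion, np.random.default_rng(0)) == []


def test_coarse_step_yields_fewer_than_fine_steps(bgo, bgo_tables, bgo_sampler, rng):
    """One range-sized step under-counts relative to the finely stepped path."""
    r = bgo_tables.range_at(0.42) - 1e-4
    coarse = _step_from_tables(bgo_tables, 0.42, r)
    coarse_expected = c.expected_photons(coarse, bgo.dispersion)
    # finely subdivided path integral
    fine_total = 0.0
    ke = 0.42
    for _ in range(400):
        step = min(r / 400, bgo_tables.range_at(ke) - 1e-6)
        s = _step_from_tables(bgo_tables, ke, step)
        fine_total += c.expected_photons(s, bgo.dispersion)
        ke = s.post.ke
        if ke <= bgo_tables.ke_min * 1.01:
            break
    assert coarse_expected < fine_total


def test_cone_angle_relation(bgo, bgo_tables, rng):
    """Every photon satisfies cos(theta) = 1/(beta*n(eps)) at its local beta."""
    step = _step_from_tables(bgo_tables, 0.42, 0.01)
    photons = []
    for _ in range(200):
        photons.extend(c.emit_cherenkov(step, bgo.dispersion, rng))
    assert photons
    for p in photons:
        u = np.linalg.norm(p.origin - step.pre.position) / step.length
        beta_u = step.pre.beta + u * (step.post.beta - step.pre.beta)
        n_e = float(c.refractive_index(bgo.dispersion, p.energy_ev))
        cos_theta = float(np.dot(p.direction, step.pre.direction))
        assert cos_theta == pytest.approx(1.0 / (beta_u * n_e), abs=1e-9)
        assert np.linalg.norm(p.direction) == pytest.approx(1.0, abs=1e-9)
        assert beta_u * n_e > 1.0  # never produced below local threshold
        assert bgo.dispersion.e_min <= p.energy_ev <= bgo.dispersion.e_max


def test_poisson_dispersion_of_counts(bgo, bgo_tables, bgo_sampler, rng):
    step = _step_from_tables(bgo_tables, 0.42, 0.02)
    counts = [
        len(c.emit_cherenkov(step, bgo.dispersion, rng, sampler=bgo_sampler))
        for _ in range(10000)
    ]
    counts = np.asarray(counts)
    assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.05)


def test_emission_times_and_orders(bgo, bgo_tables, rng):
    step = _step_from_tables(bgo_tables, 0.42, 0.05)
    photons = c.emit_cherenkov(step, bgo.dispersion, rng)
    while len(photons) < 3:
        photons += c.emit_cherenkov(step, bgo.dispersion, rng)
    c.assign_orders(photons)
    times = [p.emission_time for p in photons]
    orders = [p.order for p in photons]
    assert orders == list(range(1, len(photons) + 1))
    assert times == sorted(times)


def test_mean_beta_mode_uses_step_average(bgo, bgo_tables, rng):
    """Coarse mode: all photons share the step-averaged velocity cone."""
    step = _step_from_tables(bgo_tables, 0.42, 0.1)
    beta_bar = 0.5 * (step.pre.beta + step.post.beta)
    photons = []
    for _ in range(50):
        photons.extend(c.emit_cherenkov(step, bgo.dispersion, rng, mode="mean-beta"))
    assert photons
    for p in photons[:50]:
        n_e = float(c.refractive_index(bgo.dispersion, p.energy_ev))
        assert float(np.dot(p.direction, step.pre.direction)) == pytest.approx(
            1.0 / (beta_bar * n_e), abs=1e-9
        )


def test_emit_for_track_consistent_with_stepwise(bgo, bgo_tables, bgo_sampler):
    e = ElectronState.from_ke([0, 0, 10.0], [0, 0, 1], 0.420)
    track = c.propagate_electron(e, 1e-2, bgo_tables, bgo, np.random.default_rng(5))
    fast = [
        len(c.emit_for_track(track, bgo_sampler, np.random.default_rng(i))) for i in range(300)
    ]
    slow = []
    steps = track.steps
    for i in range(300):
        rng_i = np.random.default_rng(10_000 + i)
        slow.append(
            sum(len(c.emit_cherenkov(s, bgo.dispersion, rng_i, sampler=bgo_sampler)) for s in steps)
        )
    assert np.mean(fast) == pytest.approx(np.mean(slow), rel=0.1)


def test_scintillation_emission(bgo, bgo_tables, rng):
    step = _step_from_tables(bgo_tables, 0.42, 0.2)
    # no energy deposited -> no photons
    null = c.ElectronStep(step.pre, step.pre, 1e-6)
    assert c.emit_scintillation(null, rng, bgo.dispersion) == []
    photons = []
    while len(photons) < 8000:
        photons.extend(c.emit_scintillation(step, rng, bgo.dispersion, decimation=10))
    delays = np.array([p.emission_time for p in photons]) - step.pre.time
    assert delays.mean() == pytest.approx(300.0, rel=0.05)  # 300 ns decay constant
    zs = np.array([p.direction[2] for p in photons])
    assert abs(zs.mean()) < 3.0 / math.sqrt(len(zs))  # isotropic
    with pytest.raises(ValueError):
        c.emit_scintillation(step, rng, bgo.dispersion, decimation=0.5)
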