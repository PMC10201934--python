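"""Recoil-electron generation and velocity-limited stepwise transport."""

import math

import numpy as np
import pytest

import cerenkovmc as c
from cerenkovmc.transport import ElectronState, highland_theta0


def test_kinematics_values():
    assert c.kinematics(0.0) == (0.0, 1.0)
    beta, gamma = c.kinematics(0.420)
    assert beta == pytest.approx(0.83591, abs=1e-5)
    assert gamma == pytest.approx(1.82192, abs=1e-5)
    betas = [c.kinematics(k)[0] for k in (0.01, 0.1, 0.5, 1.0, 5.0)]
    assert all(a < b for a, b in zip(betas, betas[1:]))
    assert betas[-1] < 1.0


def test_interaction_depth_sampling(rng):
    mu = 0.056 * 7.13 / 10.0  # published mass attenuation x density -> 1/mm
    assert mu == pytest.approx(0.0399, abs=1e-4)
    depths = [c.sample_interaction_depth(mu, rng) for _ in range(3000)]
    assert all(0 < d <= 20.0 for d in depths)
    # untruncated exponential mean is 1/mu
    free = rng.exponential(1.0 / mu, 100_000)
    assert free.mean() == pytest.approx(1.0 / mu, rel=0.02)


def test_photoelectron_kinetic_energies(bgo, rng):
    kes = {round(c.make_photoelectron(0.511, bgo, rng).ke, 3) for _ in range(200)}
    # K-shell: 0.511 - 0.091 = 0.420 MeV; L-M pseudo-shell: ~0.503 MeV
    assert 0.420 in kes
    assert 0.503 in kes
    e1000 = c.make_photoelectron(1.000, bgo, rng)
    assert e1000.ke in (pytest.approx(0.909), pytest.approx(0.992))
    with pytest.raises(ValueError):
        c.make_photoelectron(0.05, bgo, rng)


def test_photoelectron_forward_emission(bgo, rng):
    zs = [c.make_photoelectron(0.511, bgo, rng).direction[2] for _ in range(5000)]
    assert np.mean(zs) > 0.3  # Sauter distribution tilts strongly forward


def test_limited_step_length_formula(bgo, bgo_tables):
    # velocity-change example: beta = 0.835906, 10% change -> dgamma = 0.30402
    state = ElectronState.from_ke([0, 0, 0], [0, 0, 1], 0.420)
    beta_f = state.beta * 0.9
    dgamma = state.gamma - 1.0 / math.sqrt(1.0 - beta_f**2)
    assert dgamma == pytest.approx(0.30402, abs=5e-5)
    assert 0.511 * dgamma == pytest.approx(0.15535, abs=3e-5)
    step = c.limited_step_length(state, 0.10, bgo_tables)
    assert step == pytest.approx(0.511 * dgamma / bgo_tables.dedx_at(0.420), rel=1e-9)
    with pytest.raises(ValueError):
        c.limited_step_length(state, 0.0, bgo_tables)


def test_large_delta_beta_returns_range_step(bgo, bgo_tables):
    """At 30%+ velocity change the range-based step is the binding limit."""
    _, ke_th = c.cherenkov_threshold(bgo.dispersion)
    state = ElectronState.from_ke([0, 0, 0], [0, 0, 1], 0.420)
    dx = bgo_tables.range_at(0.420) - bgo_tables.range_at(ke_th)
    for db in (0.4, 0.6, 0.9, None):
        assert c.limited_step_length(state, db, bgo_tables, cerenkov_ke_min=ke_th) == pytest.approx(
            dx, rel=1e-12
        )
    # at small delta_beta the velocity limit binds instead
    assert c.limited_step_length(state, 4e-4, bgo_tables, cerenkov_ke_min=ke_th) < 0.01 * dx


def test_scatter_direction_statistics(bgo, rng):
    state = ElectronState.from_ke([0, 0, 0], [0, 0, 1], 0.42)
    # Highland width grows like sqrt(step)
    t_small = highland_theta0(0.42, state.beta, 2e-4, bgo.radiation_length_mm)
    t_large = highland_theta0(0.42, state.beta, 2e-1, bgo.radiation_length_mm)
    assert t_large > 10 * t_small
    # sampled mean deflection cosine matches the Gaussian expectation exp(-theta0^2/2)
    step = 2e-3
    theta0 = highland_theta0(0.42, state.beta, step, bgo.radiation_length_mm)
    cos_mean = np.mean(
        [np.dot(c.scatter_direction(state, step, bgo, rng), state.direction) for _ in range(10000)]
    )
    assert cos_mean == pytest.approx(math.exp(-(theta0**2) / 2.0), abs=0.02)
    norm = np.linalg.norm(c.scatter_direction(state, step, bgo, rng))
    assert norm == pytest.approx(1.0, abs=1e-9)


def test_unlimited_track_structure(bgo, bgo_tables, rng):
    """Unlimited velocity change: two steps, first one near the CSDA range."""
    _, ke_th = c.cherenkov_threshold(bgo.dispersion)
    firsts, nsteps = [], []
    for _ in range(50):
        e = c.make_photoelectron(0.511, bgo, rng)
        tr = c.propagate_electron(e, None, bgo_tables, bgo, rng)
        firsts.append(tr.length[0])
        nsteps.append(tr.n_steps)
    assert np.mean(nsteps) == pytest.approx(2.0, abs=0.2)
    k_firsts = [f for f in firsts if f < 0.36]  # K-shell population
    assert np.mean(k_firsts) == pytest.approx(0.348, rel=0.15)


def test_small_delta_beta_track_structure(bgo, bgo_tables, rng):
    e = ElectronState.from_ke([0, 0, 10.0], [0, 0, 1], 0.420)
    tr = c.propagate_electron(e, 4e-4, bgo_tables, bgo, rng)
    assert 1000 < tr.n_steps < 3000
    mean_um = tr.mean_step_length_mm * 1000
    assert 0.1 < mean_um < 0.4  # ~0.2 um scale


def test_track_energy_bookkeeping(bgo, bgo_tables, rng):
    e = c.make_photoelectron(0.511, bgo, rng)
    tr = c.propagate_electron(e, 1e-2, bgo_tables, bgo, rng)
    dke = tr.pre_ke - tr.post_ke
    assert dke.sum() == pytest.approx(e.ke - tr.post_ke[-1], abs=1e-6)
    # steps are contiguous: post state of step i is pre state of step i+1
    np.testing.assert_allclose(tr.post_ke[:-1], tr.pre_ke[1:], rtol=1e-12)
    np.testing.assert_allclose(tr.post_time[:-1], tr.pre_time[1:], rtol=1e-12)
    # geometry: positions advance by length along direction
    steps = tr.steps
    for s in steps[:10]:
        np.testing.assert_allclose(
            np.linalg.norm(s.post.position - s.pre.position), s.length, rtol=1e-9
        )
    # track length never exceeds the CSDA range
    assert tr.track_length_mm <= bgo_tables.range_at(e.ke) * (1 + 1e-6)


def test_mean_step_monotone_in_delta_beta_with_plateau(bgo, bgo_tables, rng):
    e = ElectronState.from_ke([0, 0, 10.0], [0, 0, 1], 0.420)
    means = []
    tracklens = []
    for db in (1e-3, 1e-2, 0.1, 0.3, 0.6, None):
        lens = []
        tl = []
        for _ in range(25):
            tr = c.propagate_electron(e, db, bgo_tables, bgo, rng)
            lens.append(tr.mean_step_length_mm)
            tl.append(tr.track_length_mm)
        means.append(np.mean(lens))
        tracklens.append(np.mean(tl))
    assert all(a < b * 1.01 for a, b in zip(means, means[1:]))  # non-decreasing
    # plateau: 30%+ equals the unlimited value
    assert means[3] == pytest.approx(means[-1], rel=1e-6)
    assert means[4] == pytest.approx(means[-1], rel=1e-6)
    # mean track length is independent of the velocity-change limit
    assert max(tracklens) - min(tracklens) < 2e-3 * np.mean(tracklens) + 1e-6


def test_loglog_linearity_of_mean_step(bgo, bgo_tables, rng):
    """log(mean step) vs log(delta_beta) is ~linear in the limited regime."""
    e = ElectronState.from_ke([0, 0, 10.0], [0, 0, 1], 0.420)
    dbs = np.array([2e-3, 1e-2, 5e-2])
    means = []
    for db in dbs:
        tr = c.propagate_electron(e, float(db), bgo_tables, bgo, rng)
        means.append(tr.mean_step_length_mm)
    slope = np.polyfit(np.log(dbs), np.log(means), 1)[0]
    assert slope == pytest.approx(1.0, abs=0.25)
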