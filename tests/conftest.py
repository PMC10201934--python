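import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cerenkovmc as c

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bgo():
    return c.make_bgo()


@pytest.fixture(scope="session")
def tlbr():
    return c.make_tlbr()


@pytest.fixture(scope="session")
def bgo_tables(bgo):
    return c.build_loss_tables(bgo)


@pytest.fixture(scope="session")
def bgo_sampler(bgo):
    return c.CerenkovSampler(bgo.dispersion)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_delta_beta_run(bgo, bgo_tables, bgo_sampler):
    """Shared 0.04% velocity-limit run (200 events, emission only)."""
    summary, raw = c.run_single(
        bgo, 4e-4, 200, seed=2026, tables=bgo_tables, sampler=bgo_sampler,
        optical_transport=False,
    )
    return summary, raw


@pytest.fixture(scope="session")
def unlimited_run(bgo, bgo_tables, bgo_sampler):
    """Shared unlimited-step run (300 events, emission only, coarse yield)."""
    summary, raw = c.run_single(
        bgo, None, 300, seed=2027, tables=bgo_tables, sampler=bgo_sampler,
        optical_transport=False, yield_mode="mean-beta",
    )
    return summary, raw
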