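"""Shared fixtures: oscillator models with precomputed cycles and isochrons.

The heavy objects (shooting solutions, PPV/Hessian grids, SSA sample paths)
are session-scoped so the whole suite pays for each of them once.
"""

import numpy as np
import pytest

import isophase as ip
from isophase.phase_schemes import SchemeOptions


@pytest.fixture(scope="session")
def oracle():
    return ip.polar_oracle(c=1.0, omega=1.0)


@pytest.fixture(scope="session")
def oracle_cycle(oracle):
    return ip.find_limit_cycle(oracle, K=200)


@pytest.fixture(scope="session")
def oracle_iso(oracle, oracle_cycle):
    iso = ip.compute_ppv(oracle, oracle_cycle)
    ip.compute_phase_hessian(oracle, oracle_cycle, iso)
    return iso


@pytest.fixture(scope="session")
def brusselator():
    return ip.brusselator_model()


@pytest.fixture(scope="session")
def brusselator_cycle(brusselator):
    return ip.find_limit_cycle(brusselator, K=400)


@pytest.fixture(scope="session")
def brusselator_iso(brusselator, brusselator_cycle):
    iso = ip.compute_ppv(brusselator, brusselator_cycle)
    ip.compute_phase_hessian(brusselator, brusselator_cycle, iso)
    return iso


@pytest.fixture(scope="session")
def brusselator_4x():
    """Brusselator at 4x volume with reservoir counts scaled along."""
    return ip.brusselator_model(volume=1000.0, A_count=28, B_count=20)


@pytest.fixture(scope="session")
def brusselator_4x_cycle(brusselator_4x):
    return ip.find_limit_cycle(brusselator_4x, K=400)


@pytest.fixture(scope="session")
def brusselator_4x_iso(brusselator_4x, brusselator_4x_cycle):
    return ip.compute_ppv(brusselator_4x, brusselator_4x_cycle)


@pytest.fixture(scope="session")
def oregonator():
    return ip.oregonator_model()


@pytest.fixture(scope="session")
def oregonator_cycle(oregonator):
    return ip.find_limit_cycle(oregonator, K=800)


@pytest.fixture(scope="session")
def oregonator_iso(oregonator, oregonator_cycle):
    iso = ip.compute_ppv(oregonator, oregonator_cycle)
    ip.compute_phase_hessian(oregonator, oregonator_cycle, iso)
    return iso


@pytest.fixture(scope="session")
def bruss_ssa_period(brusselator, brusselator_cycle):
    """One period of an SSA path started on the cycle (fixed seed)."""
    x0 = np.round(brusselator_cycle.samples[0])
    return ip.simulate_ssa(brusselator, x0=x0,
                           t_end=brusselator_cycle.period, seed=0)


@pytest.fixture(scope="session")
def scheme_opts():
    """Scheme options with the Fourier grid matched to the fixtures' waveforms."""
    return SchemeOptions(fourier_grid=2048)
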