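import numpy as np
import pytest

from confspace.distributions import (DistanceDistribution, make_continuous,
                                     normalize_unit_area)
from confspace.sampler import ProtocolConfig
from confspace.synthetic import make_benchmark


def discrete_gaussian(mu=30.0, sigma=3.0, step=0.5, span=6.0, label="g"):
    """Discrete unit-area Gaussian distribution (trapezoid-normalized)."""
    r = np.arange(mu - span * sigma, mu + span * sigma + step / 2, step)
    p = np.exp(-0.5 * ((r - mu) / sigma) ** 2)
    return normalize_unit_area(DistanceDistribution(r=r, p=p, label=label))


@pytest.fixture
def gauss_dist():
    return discrete_gaussian()


@pytest.fixture
def gauss_cont(gauss_dist):
    return make_continuous(gauss_dist)


@pytest.fixture(scope="session")
def benchmark():
    """The packaged synthetic benchmark: 2 bodies, 2-state truth, 6 pairs."""
    system, truth, dists, restraints = make_benchmark(seed=1)
    return system, truth, dists, restraints


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small protocol for fast functional tests."""
    return ProtocolConfig(n_iterations=3, n_calculated=4, n_selected=2,
                          anneal_steps=120, rng_seed=7)


@pytest.fixture(scope="session")
def benchmark_cfg():
    """Scaled validation protocol (50 iterations x 20 calculated / 4 kept)."""
    return ProtocolConfig(n_iterations=50, n_calculated=20, n_selected=4,
                          anneal_steps=600, rng_seed=1)
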