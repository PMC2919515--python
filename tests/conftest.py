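import numpy as np
import pytest

import interpot as ip


@pytest.fixture(scope="session")
def uniform_q():
    """Uniform state density on [0, 10]: the simplest analytic null."""
    return ip.StateDensity.uniform(0.0, 10.0)


@pytest.fixture(scope="session")
def small_context():
    """A down-scaled circles-in-a-square context for fast unit tests."""
    spec = ip.ScenarioSpec(domain_size=(80.0, 80.0), M=16, R=3.57, N=50, seed=123)
    Y, domain = ip.generate_circles(spec)
    q = ip.estimate_state_density(domain, Y, grid_spacing=0.5)
    return {"spec": spec, "Y": Y, "domain": domain, "q": q}


@pytest.fixture(scope="session")
def benchmark_context():
    """The benchmark context: M=100 circles, R=3.57, 200x200 square domain."""
    spec = ip.ScenarioSpec(seed=42)
    Y, domain = ip.generate_circles(spec)
    q = ip.estimate_state_density(domain, Y, grid_spacing=0.25)
    return {"spec": spec, "Y": Y, "domain": domain, "q": q}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
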