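import numpy as np
import pytest

from hvgchaos.hvg import build_hvg, degree_distribution


@pytest.fixture(scope="session")
def white_noise_values():
    """One seeded uniform white-noise series of length 1e5."""
    rng = np.random.default_rng(20140923)
    return rng.uniform(size=100_000)


@pytest.fixture(scope="session")
def white_noise_graph(white_noise_values):
    return build_hvg(white_noise_values)


@pytest.fixture(scope="session")
def white_noise_dist(white_noise_graph):
    return degree_distribution(white_noise_graph)
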