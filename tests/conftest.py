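import numpy as np
import pytest

from peldock.synthetic import make_restraint_experiment, make_two_domain_toy


@pytest.fixture(scope="session")
def toy_domains():
    """A fixed/mobile helical-bundle pair at a known clash-free pose."""
    return make_two_domain_toy(seed=1)


@pytest.fixture(scope="session")
def benchmark(toy_domains):
    """Noise-free 16-restraint synthetic experiment on the toy complex."""
    fixed, mobile, pose = toy_domains
    return make_restraint_experiment(fixed, mobile, pose,
                                     noise_sigma_trace=0.0, seed=1)


@pytest.fixture(scope="session")
def small_benchmark():
    """A lighter benchmark (smaller domains, 8 pairs) for expensive loops."""
    fixed, mobile, pose = make_two_domain_toy(36, 36, seed=3)
    return make_restraint_experiment(fixed, mobile, pose, n_pairs=8,
                                     noise_sigma_trace=0.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
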