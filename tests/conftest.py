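import numpy as np
import pytest

from ontotraj.config import RunConfig
from ontotraj.simulate import SimSpec, simulate


@pytest.fixture(scope="session")
def cfg():
    return RunConfig(seed=1, n_permutations=499)


@pytest.fixture(scope="session")
def noiseless_sim():
    return simulate(SimSpec(n_species=8, noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def noisy_sim():
    return simulate(SimSpec(n_species=10, noise_sd=0.05, seed=7))
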