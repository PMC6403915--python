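import numpy as np
import pytest

from polyscission import ModelParams


@pytest.fixture
def params():
    """Reference film parameters with the non-irradiated kinetic constant."""
    return ModelParams(kd=3.85e-5, Mn_ref=406_000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_valid_moments(rng, n=1):
    """Random moment triples satisfying mu1 >= mu0 and PD >= 1."""
    mu0 = 10.0 ** rng.uniform(-7, -5, n)
    mean_len = 10.0 ** rng.uniform(0.5, 3, n)
    mu1 = mu0 * mean_len
    pd = 1.0 + rng.uniform(0.0, 1.5, n)
    mu2 = pd * mu1 ** 2 / mu0
    return mu0, mu1, mu2
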