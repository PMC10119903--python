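import numpy as np
import pytest

from simexsel import ObservedSample, SimulationDesign, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tame_sample(rng):
    """A small, well-posed observational sample: two error-prone and one
    error-free covariate, moderate effects, no positivity problems."""
    n = 300
    X = rng.standard_normal((n, 2))
    Z = rng.standard_normal((n, 1))
    eta = 0.3 + 0.8 * X[:, 0] - 0.5 * Z[:, 0]
    T = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    Y = T + X[:, 0] + 0.5 * Z[:, 0] + rng.standard_normal(n)
    Xstar = X + np.sqrt(0.2) * rng.standard_normal((n, 2))
    return ObservedSample(T=T, Y=Y, Xstar=Xstar, Z=Z)


@pytest.fixture
def benchmark_design():
    """The full simulation design (n=400, 15+15 covariates, additive error)."""
    return SimulationDesign(sigma_e2=0.15)


@pytest.fixture
def benchmark_draw():
    d = SimulationDesign(sigma_e2=0.15, seed=11)
    return generate_dataset(d)
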