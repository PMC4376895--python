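import warnings

import numpy as np
import pytest

import splanova as sp


@pytest.fixture(scope="session")
def unit_measures():
    """Lebesgue probability measures on [0,1]^2, order 32."""
    return (
        sp.make_measure("lebesgue", (0.0, 1.0), order=32),
        sp.make_measure("lebesgue", (0.0, 1.0), order=32),
    )


@pytest.fixture(scope="session")
def grid21():
    g = np.linspace(0.0, 1.0, 21)
    XX, YY = np.meshgrid(g, g, indexing="ij")
    return g, np.column_stack([XX.ravel(), YY.ravel()])


def make_example1_obs(n, noise_sd, seed):
    rng = np.random.default_rng(seed)
    x = rng.random((n, 2))
    z = sp.true_function("example1", x[:, 0], x[:, 1])
    z = z + rng.normal(0.0, noise_sd, n)
    return sp.Observations(x, z)


@pytest.fixture(scope="session")
def tps_fit_400(unit_measures):
    """A well-resolved thin-plate fit of example 1 (n=400, low noise)."""
    obs = make_example1_obs(400, 0.05, 101)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sp.fit_spline(sp.make_tps_kernel(), obs)
    return fit


@pytest.fixture(scope="session")
def tps_decomp_400(tps_fit_400, unit_measures):
    return sp.posthoc_decompose(tps_fit_400, unit_measures)


@pytest.fixture(scope="session")
def tensor_fit_100(unit_measures):
    """Tensor-product SS-ANOVA fit of a noisy example-1 sample."""
    obs = make_example1_obs(100, 0.5, 7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit, dec = sp.classic_ssanova(obs, measures=unit_measures)
    return fit, dec
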