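import numpy as np
import pytest

from activediff.analytic_scores import GaussianMixture
from activediff.sde_core import ActiveParams, PassiveParams


@pytest.fixture
def passive_params() -> PassiveParams:
    return PassiveParams(k=1.0, T=1.0)


@pytest.fixture
def active_params() -> ActiveParams:
    return ActiveParams(k=1.0, Tp=0.1, Ta=1.0, tau=2.0)


@pytest.fixture
def gmm_1d_two() -> GaussianMixture:
    return GaussianMixture(
        weights=[0.4, 0.6], means=[[-1.0], [1.0]], variances=[[0.09], [0.09]]
    )


@pytest.fixture
def gmm_1d_three() -> GaussianMixture:
    return GaussianMixture(
        weights=[0.2, 0.5, 0.3],
        means=[[-1.5], [0.0], [2.0]],
        variances=[[0.2], [0.1], [0.3]],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
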