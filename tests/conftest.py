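import numpy as np
import pytest

from ecoevodiv import Community, ModelParams, SpeciesState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params_1d():
    return ModelParams(L=1, omega=0.15, theta=0.5, mortality_shape="quadratic")


@pytest.fixture
def two_species_1d(params_1d):
    """A small asymmetric 1-D community used across modules."""
    return Community(
        params_1d,
        [
            SpeciesState(N=0.8, mu=[-0.2], G=[[0.01]], E=[[0.004]]),
            SpeciesState(N=1.2, mu=[0.25], G=[[0.006]], E=[[0.003]]),
        ],
    )
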