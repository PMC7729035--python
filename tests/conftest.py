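import numpy as np
import pytest

from biotrio import ModelParameters, PopulationState, SimulationSettings, simulate


@pytest.fixture
def defaults() -> ModelParameters:
    return ModelParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def sinusoid_trajectory():
    """Reference long run in the sustained-oscillation regime (k3 = 1)."""
    return simulate(
        ModelParameters(k3=1.0),
        SimulationSettings(t_end=200.0, dt_out=0.025),
    )


def random_params(rng: np.random.Generator, with_hopf: bool = True) -> ModelParameters:
    """Random positive parameter set; optionally constrained so a positive
    Hopf point k1*N - k4 - k5 > 0 exists."""
    while True:
        p = ModelParameters(
            k1=rng.uniform(0.2, 2.0),
            k2=rng.uniform(0.2, 2.0),
            k3=rng.uniform(0.2, 2.0),
            k4=rng.uniform(0.2, 2.0),
            k5=rng.uniform(0.2, 2.0),
            N=rng.uniform(1.0, 6.0),
        )
        if not with_hopf or p.k1 * p.N - p.k4 - p.k5 > 0.3:
            return p
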