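import numpy as np
import pytest

from micellab import (
    KineticParams,
    MassNoiseModel,
    PopulationParams,
    build_population,
    sample_mp_events,
)


@pytest.fixture(scope="session")
def default_params() -> PopulationParams:
    return PopulationParams()


@pytest.fixture(scope="session")
def kinetic_params() -> KineticParams:
    return KineticParams()


@pytest.fixture(scope="session")
def pop_30um(default_params):
    """Default near-neutral population at 30 μM."""
    return build_population(default_params, 30.0, "pH8")


@pytest.fixture(scope="session")
def noiseless_events(pop_30um):
    """20k landing events with measurement noise switched off."""
    return sample_mp_events(pop_30um, 20_000, noise=MassNoiseModel(0.0, 0.0), seed=3)
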