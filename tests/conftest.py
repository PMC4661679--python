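import numpy as np
import pytest

from poolsim import OutcomeParams, PopulationParams, ScenarioSpec, build_population


@pytest.fixture(scope="session")
def small_population():
    """A fully built population of 60k records (linear model, light ME)."""
    spec = ScenarioSpec(
        model_form="linear", beta1=0.25, sigma2_1=0.0625,
        n_pop=60_000, seed=123,
    )
    return build_population(spec)


@pytest.fixture(scope="session")
def viable_population(small_population):
    return small_population[small_population["viable"]].reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
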