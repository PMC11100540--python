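import numpy as np
import pytest

from wmgate.design import build_design
from wmgate.simulate import (
    MixturePopulation,
    assign_imaginary_ltm_colors,
    simulate_population,
)


@pytest.fixture(scope="session")
def e1_schedule():
    return build_design("E1", seed=101)


@pytest.fixture(scope="session")
def e3_schedule():
    return build_design("E3", seed=103)


@pytest.fixture(scope="session")
def e4_schedule():
    sched = build_design("E4", seed=104)
    return assign_imaginary_ltm_colors(sched, seed=204)


@pytest.fixture(scope="session")
def small_mixture_cohort():
    """A small reproduction cohort reused by several mixture-model tests."""
    pop = MixturePopulation.from_probs([0.6, 0.15, 0.15, 0.1], 10.0)
    return simulate_population(pop, 6, seed=77)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
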