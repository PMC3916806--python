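import numpy as np
import pytest

from cstlong import CohortDesign, default_scenario, simulate_cohort


@pytest.fixture(scope="session")
def small_design():
    """A reduced cohort (8 + 6 subjects, shortened schedules) for fast tests."""
    return CohortDesign(
        n_nonpregnant=8,
        n_pregnant=6,
        nonpregnant_schedule=tuple(0.5 * k for k in range(1, 17)),  # 8 weeks
        pregnant_schedule=(8.0, 12.0, 16.0, 20.0, 24.0, 26.0, 28.0, 30.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return small_cohort[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_states(rng, n, dim):
    """n random community states of given dimension (strictly positive)."""
    return rng.dirichlet(np.full(dim, 0.7), size=n)
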