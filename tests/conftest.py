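import pytest

from hsequity import SimulationSpec, cem_match, simulate_cohort

MATCHING = ("age_group", "gender", "income_quintile", "sah")


@pytest.fixture(scope="session")
def small_sim():
    """A small default-condition cohort: 20 cities x 3 communities x 12 workers."""
    spec = SimulationSpec(
        n_cities=20, communities_per_city=3, workers_per_community=12, seed=424242
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return small_sim.cohort


@pytest.fixture(scope="session")
def matched_small(small_cohort):
    return cem_match(small_cohort, list(MATCHING))
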