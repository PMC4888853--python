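import pytest

from pedburden.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-gene cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(
        seed=11, n_families=6, n_background_genes=15,
        n_cohort_controls=30))


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return small_sim.cohort
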