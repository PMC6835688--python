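import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "derandomized",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("derandomized")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def e2_config():
    from ocusearch.stimuli import experiment_config

    return experiment_config("E2")


@pytest.fixture(scope="session")
def small_e2_session():
    """A reduced E2 session (all nine cells, few trials) for pipeline tests."""
    from ocusearch.stimuli import SessionSpec, experiment_config, standard_cells

    return SessionSpec(experiment_config("E2"), standard_cells("E2"), 5, rng_seed=11)


@pytest.fixture(scope="session")
def small_e2_log(small_e2_session):
    from ocusearch.observer import get_preset, simulate_cohort
    from ocusearch.stimuli import schedule_session

    trials = schedule_session(small_e2_session)
    return simulate_cohort(trials, 3, 99, params=get_preset("paper_like_E2"))
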