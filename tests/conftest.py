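import pytest

from safeloop import LoopConfig, generate_cohort, run_scenario, scenario_c


@pytest.fixture(scope="session")
def cohort3():
    return generate_cohort(3, seed=1)


@pytest.fixture(scope="session")
def one_patient(cohort3):
    return cohort3[0]


@pytest.fixture(scope="session")
def short_c_result(cohort3):
    """Scenario C, 2 days, all four arms, 3 patients — shared across tests."""
    sc = scenario_c(days=2)
    return run_scenario(sc, cohort3, seed=11, cfg=LoopConfig())
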