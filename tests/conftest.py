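import pytest
from hypothesis import HealthCheck, settings

from carecase import (AsthmaParams, EconomicAssumptions, MammographyParams,
                      compare_hedis_scenarios, compare_med_use_scenarios)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mammo_params() -> MammographyParams:
    return MammographyParams()


@pytest.fixture(scope="session")
def asthma_params() -> AsthmaParams:
    return AsthmaParams()


@pytest.fixture(scope="session")
def assumptions() -> EconomicAssumptions:
    return EconomicAssumptions()


@pytest.fixture(scope="session")
def mammo_base_delta(mammo_params):
    """Base-case 70% -> 80% comparison, shared across tests."""
    return compare_hedis_scenarios(mammo_params, 0.70, 0.80)


@pytest.fixture(scope="session")
def asthma_outputs(asthma_params):
    """Adult scenario runs at the four published rates, shared across tests."""
    from carecase import run_asthma_scenario
    return {r: run_asthma_scenario(asthma_params, r, 60, "adult")
            for r in (0.60, 0.70, 0.80, 0.90)}


@pytest.fixture(scope="session")
def asthma_child_outputs(asthma_params):
    from carecase import run_asthma_scenario
    return {r: run_asthma_scenario(asthma_params, r, 60, "child")
            for r in (0.60, 0.70, 0.80, 0.90)}


@pytest.fixture(scope="session")
def asthma_base_delta(asthma_params):
    return compare_med_use_scenarios(asthma_params, 0.80, 0.90, 60, "adult")
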