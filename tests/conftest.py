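import pytest
from hypothesis import HealthCheck, settings

from hbp_bia import engine
from hbp_bia.params import default_parameters

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def projection(params):
    return engine.default_projection(params, seed=0)


@pytest.fixture(scope="session")
def scenarios(params):
    return engine.default_scenarios(params)


@pytest.fixture(scope="session")
def baseline_run(params, projection, scenarios):
    return engine.run_scenario(scenarios[0], params, projection)


@pytest.fixture(scope="session")
def new_run(params, projection, scenarios):
    return engine.run_scenario(scenarios[1], params, projection)


@pytest.fixture(scope="session")
def impact(params, baseline_run, new_run):
    return engine.budget_impact(baseline_run, new_run, params.cpi_by_year)


@pytest.fixture(scope="session")
def small_psa(params):
    """A modest PSA shared across tests (reproducible, seed 7)."""
    return engine.run_psa(params, n_iter=300, seed=7)
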