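import pytest
from hypothesis import HealthCheck, settings

from cmm_bia import builtin_croatia_scenario, project_enrollment, run_model

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def croatia():
    """Built-in Croatia scenario, published-tables replication mode."""
    return builtin_croatia_scenario("published_tables")


@pytest.fixture(scope="session")
def croatia_stated():
    """Built-in Croatia scenario with the parameter tables taken literally."""
    return builtin_croatia_scenario("as_stated")


@pytest.fixture(scope="session")
def projection(croatia):
    return project_enrollment(croatia)


@pytest.fixture(scope="session")
def result(croatia):
    """Full published-tables model run."""
    return run_model(croatia)


@pytest.fixture(scope="session")
def result_stated(croatia_stated):
    return run_model(croatia_stated)
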