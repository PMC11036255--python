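import pytest
from hypothesis import HealthCheck, settings

import nafld_ce as nc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_params():
    return nc.base_case_parameters()


@pytest.fixture(scope="session")
def base_results(base_params):
    """One StrategyResult per strategy on the packaged base case."""
    return {s: nc.run_strategy(base_params, s) for s in nc.STRATEGIES}


@pytest.fixture(scope="session")
def no_death():
    return nc.degenerate_fixture("no_death")


@pytest.fixture(scope="session")
def two_state():
    return nc.degenerate_fixture("two_state")


@pytest.fixture(scope="session")
def single_path():
    return nc.degenerate_fixture("single_path")
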