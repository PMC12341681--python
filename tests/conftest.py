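import pytest
from hypothesis import HealthCheck, settings

from fluxbridge import synthetic_fixtures as sf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def chain():
    """3-reaction linear chain with inflow 1 mM/s: steady flux 1 everywhere."""
    return sf.make_linear_chain(n=3, k_in=1.0, seed=0)


@pytest.fixture(scope="session")
def branch():
    """Glucose-splitting growth/product motif at the reference conditions."""
    return sf.make_branch_fixture()


@pytest.fixture(scope="session")
def zoo():
    """One reaction pair per mapping category."""
    return sf.make_category_zoo()


@pytest.fixture(scope="session")
def branch_steady(branch):
    from fluxbridge import simulate_to_steady_state

    kinetic, _, _ = branch
    return simulate_to_steady_state(kinetic, growth_reaction_id="BIOMASS")
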