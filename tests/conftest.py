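import pytest
from hypothesis import HealthCheck, settings

from rholoop.egfr_network import cyclic_hierarchy, curated_network, switch_hierarchy

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def net_cyclic():
    """Curated network under the accepted pseudo-oscillatory hierarchy."""
    return curated_network(cyclic_hierarchy())


@pytest.fixture(scope="session")
def net_switch():
    """Curated network under the Rac1-to-RhoA switch hierarchy."""
    return curated_network(switch_hierarchy())


@pytest.fixture(scope="session")
def full_screen():
    """Knockout screen over both accepted hierarchies (computed once)."""
    from rholoop.perturbation import run_screen

    return run_screen(curated_network, [cyclic_hierarchy(), switch_hierarchy()])
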