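import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures_by_name():
    from izhifit.workbench import load_fixtures

    return {e.name: e for e in load_fixtures()}


@pytest.fixture(scope="session")
def orlm(fixtures_by_name):
    """CA1 OR-LM single-compartment reference model (NASP)."""
    return fixtures_by_name["CA1 OR-LM"]


@pytest.fixture(scope="session")
def mc_entry():
    from izhifit.workbench import load_mc_fixture

    return load_mc_fixture()


@pytest.fixture(scope="session")
def criteria():
    from izhifit.workbench import default_criteria

    return default_criteria()


@pytest.fixture(scope="session")
def accurate_sim():
    from izhifit.model import SimConfig

    return SimConfig(dt=0.05, duration=1100.0, method="rk4")


@pytest.fixture(scope="session")
def orlm_trace_156(orlm, accurate_sim):
    """One shared accurate simulation of the OR-LM model at 156 pA."""
    from izhifit.model import Stimulus
    from izhifit.simulate import simulate

    stim = Stimulus.step(156.0, 100.0, accurate_sim.duration, target="soma")
    return simulate(orlm.model, stim, accurate_sim)
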