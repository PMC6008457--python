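import numpy as np
import pytest

from hepatodyn.demo import (build_demo_model, default_demo_boundary,
                            mean_boundary)
from hepatodyn.simulate import compile_model, find_steady_state, simulate


@pytest.fixture(scope="session")
def demo_model():
    return build_demo_model()


@pytest.fixture(scope="session")
def demo_compiled(demo_model):
    return compile_model(demo_model)


@pytest.fixture(scope="session")
def demo_boundary():
    return default_demo_boundary()


@pytest.fixture(scope="session")
def demo_mean(demo_boundary):
    return mean_boundary(demo_boundary)


@pytest.fixture(scope="session")
def demo_steady(demo_model, demo_compiled, demo_mean):
    return find_steady_state(demo_model, demo_mean, compiled=demo_compiled)


@pytest.fixture(scope="session")
def diurnal_traj(demo_model, demo_compiled, demo_boundary, demo_steady):
    """Three run-in days, then the analyzed 24 h window."""
    return simulate(demo_model, demo_boundary, (0.0, 96.0),
                    t_eval=np.linspace(72.0, 96.0, 481),
                    x0=demo_steady.state, compiled=demo_compiled)


@pytest.fixture(scope="session")
def warm_state(diurnal_traj):
    """Species-keyed state on the diurnal attractor (for scenario runs)."""
    return diurnal_traj.state_dict(0)


@pytest.fixture(scope="session")
def hypoxia_table(demo_model, demo_compiled, demo_mean):
    from hepatodyn.scenarios import hypoxia_scan
    grid = [80, 60, 40, 25, 15, 8, 3, 1]
    return hypoxia_scan(demo_model, grid, demo_mean, compiled=demo_compiled)


@pytest.fixture(scope="session")
def ethanol_run(demo_model, demo_boundary, warm_state):
    from hepatodyn.scenarios import InfusionProfile, ethanol_bolus
    inf = InfusionProfile.bolus("etoh_ext", 80.0, 2.0, 3.0)
    return ethanol_bolus(demo_model, demo_boundary, inf, x0=warm_state)


@pytest.fixture(scope="session")
def galactosemia_table(demo_model, demo_boundary, warm_state):
    from hepatodyn.scenarios import compare_galactosemia
    return compare_galactosemia(demo_model, demo_boundary, x0=warm_state)


@pytest.fixture(scope="session")
def vpa_run(demo_model, demo_boundary, warm_state):
    from hepatodyn.scenarios import vpa_scenario
    return vpa_scenario(demo_model, demo_boundary, x0=warm_state)
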