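import warnings

import numpy as np
import pytest

import meioswitch as ms
from meioswitch import NutrientSchedule, default_parameters

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", message=".*lsoda.*")


@pytest.fixture(scope="session")
def meiosis_params():
    return default_parameters("meiosis")


@pytest.fixture(scope="session")
def integrated_params():
    return default_parameters("integrated")


@pytest.fixture(scope="session")
def wt_rich_state(meiosis_params):
    """Resting (nutrient-rich) state of the wild-type subsystem."""
    m = ms.MeiosisModel(meiosis_params, NutrientSchedule.rich())
    return m.steady_state(0.0)


@pytest.fixture(scope="session")
def wt_starved_run(meiosis_params, wt_rich_state):
    """Wild-type starvation trajectory (starvation from t = 0)."""
    m = ms.MeiosisModel(meiosis_params, NutrientSchedule.constant(0.0, 0.75))
    return ms.simulate(m, 700.0, y0=wt_rich_state, dt=1.0)


@pytest.fixture(scope="session")
def screen_df(meiosis_params):
    """Full mutant screen over the bundled registry (slow; shared)."""
    return ms.run_screen(params=meiosis_params)


@pytest.fixture(scope="session")
def cycling_state(integrated_params):
    m = ms.IntegratedModel(integrated_params, NutrientSchedule.rich())
    return m.cycling_state()


def relax(model, y0, t=2000.0):
    """Relax a model along its flow with inputs frozen at t = 0."""
    from scipy.integrate import solve_ivp
    sol = solve_ivp(lambda tt, yy: model.rhs(0.0, yy), (0.0, t), y0,
                    method="LSODA", rtol=1e-8, atol=1e-10)
    return np.maximum(sol.y[:, -1], 0.0)
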