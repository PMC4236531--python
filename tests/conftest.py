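import numpy as np
import pytest

import capgap as cg
from capgap.kinetics import ACTIVITIES


@pytest.fixture(scope="session")
def model():
    return cg.planar9()


@pytest.fixture(scope="session")
def trials(model):
    """One synthetic trial per activity, fixed seeds."""
    return {
        act: cg.generate_trial(cg.default_profile(act, seed=1 + i), model)
        for i, act in enumerate(ACTIVITIES)
    }


@pytest.fixture(scope="session")
def sweeps(model, trials):
    """Full 0-100% weakness sweep of every activity (shared: ~6 s)."""
    return {act: cg.weakness_sweep(model, trial) for act, trial in trials.items()}


@pytest.fixture(scope="session")
def stair_solution(model, trials):
    """Static-optimization solution of stair ascent at full strength."""
    return cg.solve_trial(model, trials["stair_ascent"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
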