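import numpy as np
import pytest

from myoloop.emg import BayesParams, EMGTrace, calibrate_mv_scale
from myoloop.muscle import MuscleParams
from myoloop.plant import PlantParams
from myoloop.spindle import GammaDrive, SpindleParams
from myoloop.subject import IntentTrace, synthesize_emg


@pytest.fixture(scope="session")
def muscle_params():
    return MuscleParams()


@pytest.fixture(scope="session")
def plant_params():
    return PlantParams()


@pytest.fixture(scope="session")
def spindle_params():
    return SpindleParams()


@pytest.fixture(scope="session")
def gamma():
    return GammaDrive()


@pytest.fixture(scope="session")
def bayes_params():
    return BayesParams()


@pytest.fixture(scope="session")
def mv_scale():
    """MVC-style normalization from a 20 s maximal-effort synthetic trace."""
    cal = synthesize_emg(IntentTrace(np.ones(40000)), seed=2)
    return calibrate_mv_scale(cal)


def constant_drive_trace(x, n=20000, seed=0) -> EMGTrace:
    return synthesize_emg(IntentTrace(np.full(n, float(x))), seed=seed)
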