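import numpy as np
import pytest

from flyddm import DDMParams, Trial, TrialSet
from flyddm.extrema import EDParams


@pytest.fixture
def ddm_params():
    return DDMParams(A=1.0, k=2.0, t0=0.5, sigma0=0.1)


@pytest.fixture
def ed_params():
    return EDParams(A=0.08, k=20.0, t0=0.5, sigma0=0.1)


@pytest.fixture
def small_trialset():
    return TrialSet(
        [
            Trial(rt=1.2, choice=1, difficulty=0.3, light=0.0, fly_id="f1"),
            Trial(rt=0.8, choice=-1, difficulty=0.3, light=0.0, fly_id="f1"),
            Trial(rt=2.0, choice=1, difficulty=-1.0, light=0.01, fly_id="f2"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
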