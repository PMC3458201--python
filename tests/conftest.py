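import numpy as np
import pytest

from petkin.input_function import BiexpParams
from petkin.simulate import CohortSpec, default_frame_times, make_lesion_tac


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def default_input(default_spec):
    """Biexponential plasma input at the reference dose."""
    return default_spec.plasma_params()


@pytest.fixture(scope="session")
def frame_grid():
    mids, durations = default_frame_times()
    return mids, durations


@pytest.fixture(scope="session")
def noiseless_lesion(default_spec, default_input):
    """Noiseless mid-cohort lesion curve with its generating parameters."""
    tac, truth = make_lesion_tac(1.0, default_input, default_spec, noise_cv=0.0)
    return tac, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
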