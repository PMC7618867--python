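import numpy as np
import pytest

from gazehab.habituation_engine import HabituationConfig
from gazehab.synth_sessions import CohortSpec, SynthParams, generate_cohort


@pytest.fixture
def config():
    return HabituationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240522)


@pytest.fixture(scope="session")
def exclusion_mixture_cohort():
    """The 95-participant cohort with the canonical exclusion mixture."""
    return generate_cohort(CohortSpec(seed=95))


@pytest.fixture(scope="session")
def noiseless_params():
    """Generator settings under which the two channels agree exactly.

    Sample units must tile the 40 ms frame grid, so the gaze rate is set to
    100 Hz (10 ms units) and intended looks are snapped to the grid.
    """
    return SynthParams(
        track_loss_p=0.0,
        coder_noise_frames=0,
        look_noise_sd_s=0.0,
        frame_aligned=True,
        rate_hz=100.0,
    )
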