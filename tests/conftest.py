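import warnings

import numpy as np
import pytest

from azquant.pipeline import simulate_recording
from azquant.synthgen import SynthConfig, stim_train

warnings.filterwarnings("ignore", message="more than 10% of pixels")


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A compact recording: 40 AZs, 12 stimuli at 0.3 Hz, 45 s movie."""
    return SynthConfig(
        n_az=40, seed=7, stim_times_s=stim_train(12, 1 / 3.0), movie_duration_s=45.0,
    )


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    """One simulated recording shared by read-only tests."""
    return simulate_recording(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
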