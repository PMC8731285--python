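import numpy as np
import pytest

from pfnet.synthetic import SyntheticConfig, generate_recordings
from pfnet.windowing import segment_windows


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast dataset: short movements, 4 channels."""
    return SyntheticConfig(
        num_subjects=2,
        num_movements=3,
        num_repetitions=6,
        channels=4,
        movement_duration_s=1.0,
        rest_duration_s=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_recordings(tiny_config):
    return generate_recordings(tiny_config)


@pytest.fixture(scope="session")
def tiny_windows(tiny_recordings):
    return {
        sid: segment_windows(rec, window_ms=200, step_ms=100)
        for sid, rec in tiny_recordings.items()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
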