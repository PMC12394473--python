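import numpy as np
import pytest

from gonogo.montage import CHANNELS_10_20
from gonogo.preprocess import EPOCH_SAMPLES, EpochSet
from gonogo.synth import generate_trial_sequence


@pytest.fixture(scope="session")
def small_sequence():
    return generate_trial_sequence(40, seed=7)


@pytest.fixture(scope="session")
def default_sequence():
    return generate_trial_sequence(400, seed=1)


def make_epochset(data, conditions, valid=None, reasons=None):
    """Build an EpochSet directly from an (epochs, channels, time) array."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    time_ms = (np.arange(EPOCH_SAMPLES) - 50) * 4.0
    return EpochSet(
        data=data, time_ms=time_ms,
        condition=np.asarray(conditions, dtype=object),
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool),
        rejection_reason=(np.full(n, None, dtype=object) if reasons is None
                         else np.asarray(reasons, dtype=object)),
        channel_names=list(CHANNELS_10_20))


@pytest.fixture
def epoch_factory():
    return make_epochset
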