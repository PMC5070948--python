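import numpy as np
import pytest

from vtapipe.io import simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact mixed-prediction session reused across I/O and pipeline tests."""
    return simulate_session(
        task="mixed_prediction", n_trials=150, n_tagged=2, n_untagged=1,
        seed=11, trains_per_frequency=2,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
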