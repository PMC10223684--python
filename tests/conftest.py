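import numpy as np
import pytest

from sedpose import AlgoConfig, TriaxialRecording


@pytest.fixture
def config():
    return AlgoConfig()


def make_still_recording(orientation, duration_s=60.0, rate=100.0, noise_sd=0.0, seed=0):
    """Uniform recording of a constant gravity vector plus optional noise."""
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)
    acc = np.tile(np.asarray(orientation, dtype=float), (n, 1))
    if noise_sd > 0:
        acc = acc + rng.normal(0.0, noise_sd, size=acc.shape)
    return TriaxialRecording(t, acc[:, 0], acc[:, 1], acc[:, 2], nominal_rate=rate)


@pytest.fixture
def still_recording_factory():
    return make_still_recording
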