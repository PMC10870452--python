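import numpy as np
import pytest

from ltyseiz.synthdata import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def seizure_recording():
    """200-s recording with one ~75-s seizure at gain 5 (seed-fixed)."""
    cfg = SynthConfig(duration=200.0, n_seizures=1,
                      seizure_duration_range=(70.0, 80.0),
                      ictal_amplitude_gain=5.0, seed=7)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def quiet_recording():
    """60-s background-only recording (no seizures)."""
    cfg = SynthConfig(duration=60.0, n_seizures=0, seed=11)
    return generate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
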