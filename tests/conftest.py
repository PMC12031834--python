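import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def alpha_record():
    """Clean 20 s alpha-dominant 19-channel record plus annotations."""
    from icans_qeeg.simulate import EEGSimSpec, simulate_eeg

    spec = EEGSimSpec(duration=20.0, seed=42)
    return simulate_eeg(spec)
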