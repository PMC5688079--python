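import numpy as np
import pytest

from wiringcost.preprocessing import bandpass_notch
from wiringcost.spectral import decompose
from wiringcost.synthetic import SyntheticConfig, simulate_recording

ALPHA_FREQS = np.arange(8.0, 13.0)


@pytest.fixture(scope="session")
def coupled_decomposition():
    """Decomposition of a short strongly-coupled 4-channel simulation."""
    cfg = SyntheticConfig(n_channels=4, fs=250.0, duration_s=40.0, seed=11,
                          coupling={"EC": 0.9, "EO": 0.1})
    rec = simulate_recording(cfg, "EC")
    return decompose(bandpass_notch(rec), ALPHA_FREQS)


@pytest.fixture(scope="session")
def uncoupled_decomposition():
    cfg = SyntheticConfig(n_channels=4, fs=250.0, duration_s=40.0, seed=12,
                          coupling={"EC": 0.0, "EO": 0.0})
    rec = simulate_recording(cfg, "EC")
    return decompose(bandpass_notch(rec), ALPHA_FREQS)
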