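import numpy as np
import pandas as pd
import pytest

from gonogo import SynthParams, simulate_subject


@pytest.fixture(scope="session")
def small_params():
    """A light 2-block subject configuration without blink artifacts."""
    return SynthParams(blocks_per_subject=2, blink_rate_hz=0.0)


@pytest.fixture(scope="session")
def subject(small_params):
    """One simulated subject with EEG, shared across read-only tests."""
    return simulate_subject(small_params, seed=42)


@pytest.fixture()
def toy_trials():
    """Hand-written four-trial block covering every outcome."""
    return pd.DataFrame(
        {
            "block": [0, 0, 0, 0],
            "trial_index": [0, 1, 2, 3],
            "stimulus": ["go", "nogo", "go", "nogo"],
            "onset_ms": [0.0, 1200.0, 2400.0, 3600.0],
            "responded": [True, True, False, False],
            "rt_ms": [500.0, 450.0, np.nan, np.nan],
        }
    )
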