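import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gazeseg import ScenarioParams, simulate_recording


@pytest.fixture(scope="session")
def short_recording():
    """A 10 s simulated recording at 500 Hz with moderate noise."""
    params = ScenarioParams(duration=10.0, sigma=0.5, out_rate=500.0, seed=42)
    return simulate_recording(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
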