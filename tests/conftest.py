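import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=DeprecationWarning)

from fearlfp.simulate import SimulationParams, default_design, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One 2-tone recall session with default coupling 0.9 / lag +20 ms."""
    rec, truth = simulate_session(
        default_design("fear_recall_extinction", 2), SimulationParams(seed=7))
    return rec, truth


@pytest.fixture(scope="session")
def habituation_session():
    rec, truth = simulate_session(
        default_design("tone_habituation"), SimulationParams(seed=3))
    return rec, truth
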