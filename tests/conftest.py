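import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from _utils import noiseless_config  # noqa: E402

from corohemo.synthetic_hemo import SimConfig, simulate  # noqa: E402


@pytest.fixture(scope="session")
def sim_p0():
    """Default pump-off simulation (with noise)."""
    return simulate(SimConfig(pump_level="P0", seed=11))


@pytest.fixture(scope="session")
def sim_p8():
    """Default maximal-support simulation (with noise), slower heart rate."""
    return simulate(SimConfig(pump_level="P8", hr=64.9, seed=12))


@pytest.fixture(scope="session")
def sim_p0_clean():
    return simulate(noiseless_config(pump_level="P0", seed=11))


@pytest.fixture(scope="session")
def sim_p8_clean():
    return simulate(noiseless_config(pump_level="P8", hr=64.9, seed=12))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
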