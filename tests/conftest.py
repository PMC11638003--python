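import numpy as np
import pytest

from phypif.model import RateConstants, SystemComposition
from phypif.synthetic import PRESETS


@pytest.fixture
def p6a_rates() -> RateConstants:
    """Rate constants of the receptor core module with the minimal PIF6
    binding segment at 15 C, default red-light calibration."""
    return PRESETS["P6A"].rate_constants()


@pytest.fixture
def standard_composition() -> SystemComposition:
    """1 uM receptor with 20 nM labelled partner, the interaction-trace
    condition."""
    return SystemComposition(R0_total=1e-6, P0_total=20e-9)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
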