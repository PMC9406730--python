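import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from punctacoloc import Calibration, ChannelStack, GFP, MCHERRY, SyntheticSpec


@pytest.fixture
def calibration() -> Calibration:
    return Calibration()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220811)


def make_stack(data, name=GFP, bit_depth=16) -> ChannelStack:
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis]
    return ChannelStack(name=name, data=data.astype(np.uint16),
                        calibration=Calibration(bit_depth=bit_depth))


@pytest.fixture
def small_spec() -> SyntheticSpec:
    """A fast low-noise spec used across integration tests."""
    return SyntheticSpec(
        shape=(2, 256, 256), n_cells=20, expressing_fraction=0.8,
        p_coloc=0.5, p_mcherry_only=0.1, read_noise_sd=2.0, seed=42,
    )
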