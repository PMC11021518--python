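import numpy as np
import pandas as pd
import pytest

from pulsevar import simcell
from pulsevar.params import GrowthParams, PulseScheme


@pytest.fixture(scope="session")
def calibration():
    """Calibrated default generator parameters (computed once per session)."""
    return simcell.default_calibration()


@pytest.fixture(scope="session")
def growth():
    return GrowthParams()


@pytest.fixture(scope="session")
def small_sample(calibration, growth):
    """A modest single-pulse sample with a background sample attached."""
    rate, meas = calibration
    return simcell.simulate_cells(
        rate,
        growth,
        meas,
        [PulseScheme("HPG", 0.0, 5.0)],
        3000,
        seed=42,
        n_background=400,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240318)


def make_cell_table(lengths, signals, channel="HPG", is_background=None):
    """Minimal hand-built cell table for unit tests."""
    n = len(lengths)
    if is_background is None:
        is_background = [False] * n
    return pd.DataFrame(
        {
            "cell_id": [f"t:c{i:04d}" for i in range(n)],
            "sample_id": "t",
            "strain_id": "WT",
            "replicate": 1,
            "length_um": lengths,
            "n_nuclei": 1,
            "is_background": is_background,
            f"signal_{channel}": signals,
        }
    )
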