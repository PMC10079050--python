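import numpy as np
import pandas as pd
import pytest

from msientropy import MSIDataset, MzAxis


@pytest.fixture
def small_axis():
    return MzAxis.from_range(550.0, 570.0, 20)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_dataset(small_axis, rng):
    """5x5 grid, 20 channels, one all-zero (invalid) pixel at (4, 4)."""
    cols, rows = np.meshgrid(np.arange(5), np.arange(5))
    coords = np.column_stack([cols.ravel(), rows.ravel()])
    intens = rng.gamma(2.0, 1.0, size=(25, 20))
    intens[-1] = 0.0
    return MSIDataset(axis=small_axis, coords=coords, intensities=intens,
                      meta={"sample_id": "fixture", "pitch_um": 50.0})


@pytest.fixture
def lipid_table():
    """Reference lipid assignments with theoretical [M-H]- masses."""
    return pd.DataFrame({
        "name": ["PS(35:5)", "PE-NMe(38:5)", "PI(38:4)"],
        "formula": ["C41H70NO10P", "C44H78NO8P", "C47H83O13P"],
        "adduct": ["[M-H]-", "[M-H]-", "[M-H]-"],
        "mz": [766.4665, 778.5392, 885.5493],
    })
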