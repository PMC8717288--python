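import numpy as np
import pandas as pd
import pytest

from stemspat import TransectWindow


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


@pytest.fixture
def single_transect():
    """One 1000 m x 50 m transect (5 ha)."""
    return TransectWindow.study_design(1, 1000.0)


@pytest.fixture
def two_transects():
    return TransectWindow.study_design(2, 2000.0)


@pytest.fixture
def square_window():
    """A 1 km square; convenient when edge effects should be negligible."""
    return TransectWindow(np.array([[0.0, 1000.0, 0.0, 1000.0]]))


@pytest.fixture
def lookup():
    return pd.DataFrame(
        {
            "species": ["MUSCE", "MACMO", "PETER", "GILBE"],
            "guild": ["SLP", "SLP", "NPLD", "STS"],
            "deciduousness": ["deciduous", "deciduous", "semi-deciduous", "evergreen"],
        }
    )


@pytest.fixture
def tiny_stems():
    return pd.DataFrame(
        {
            "tree_id": ["t1", "t2", "t3", "t4", "t5"],
            "transect_id": ["T1", "T1", "T1", "T1", "T1"],
            "x": [10.0, 20.0, 30.0, 40.0, 60.0],
            "y": [5.0, 15.0, 25.0, 35.0, 45.0],
            "species": ["MUSCE", "MUSCE", "MACMO", "PETER", "GILBE"],
            "guild": ["SLP", "SLP", "SLP", "NPLD", "STS"],
            "dbh": [12.0, 36.0, 25.0, 40.0, 80.0],
        }
    )


@pytest.fixture
def subplot_grid(single_transect):
    """25 m x 50 m subplots tiling the single transect."""
    n = 40
    return pd.DataFrame(
        {
            "subplot_id": [f"T1_S{i + 1}" for i in range(n)],
            "transect_id": "T1",
            "cx": 25.0 * np.arange(n) + 12.5,
            "cy": 25.0,
            "slope_pct": 1.0,
            "topography": "flat",
            "altitude_m": 450.0,
            "dist_water_m": 100.0,
        }
    )
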