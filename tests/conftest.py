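import numpy as np
import pandas as pd
import pytest

from nodesig import simulate
from nodesig.io import NEGATIVE, POSITIVE


@pytest.fixture
def small_table():
    """6 features x 6 samples, log2 scale, with a missing pattern."""
    data = {
        "pos01": [20.0, 22.0, np.nan, 25.0, 18.0, np.nan],
        "pos02": [21.0, 23.0, 24.0, np.nan, 19.0, np.nan],
        "pos03": [20.5, 21.5, 23.5, 25.5, np.nan, np.nan],
        "neg01": [19.0, 24.0, 23.0, 24.0, 18.5, 21.0],
        "neg02": [19.5, 25.0, 22.0, 24.5, 18.0, 20.0],
        "neg03": [20.0, 24.5, np.nan, 25.0, 17.5, 22.0],
    }
    df = pd.DataFrame(data, index=[f"F{i}" for i in range(1, 7)])
    df.index.name = "feature_id"
    return df


@pytest.fixture
def small_labels(small_table):
    return {
        s: POSITIVE if s.startswith("pos") else NEGATIVE
        for s in small_table.columns
    }


@pytest.fixture
def toy_signature():
    """10-gene Epi/Mes signature used for EMT scoring tests."""
    sig = {}
    for i in range(1, 6):
        sig[f"MES{i}"] = "Mes"
        sig[f"EPI{i}"] = "Epi"
    return sig


@pytest.fixture
def planted_panel():
    """15-variable panel, 3 informative at effect 2, n = 30/30."""
    markers = tuple(f"M{i:02d}" for i in range(15))
    cfg = simulate.PanelConfig(
        markers=markers,
        layers=("protein",),
        informative_markers={"M00", "M01", "M02"},
        effect_size=2.0,
        layer_correlation=1.0,
        n_pos=30,
        n_neg=30,
        seed=11,
    )
    table, truth = simulate.generate_marker_panel(cfg)
    return table, truth
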