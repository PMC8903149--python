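import numpy as np
import pandas as pd
import pytest

from ipvalign import ItemResponseTable, generate
from ipvalign.synthetic_data import invariance_benchmark_spec


@pytest.fixture
def tiny_table() -> ItemResponseTable:
    """3 respondents, 2 groups, 2 items, no missingness."""
    df = pd.DataFrame(
        {
            "group": ["A", "A", "B"],
            "weight": [1.0, 2.0, 1.0],
            "x1": [1.0, 0.0, 1.0],
            "x2": [0.0, 0.0, 1.0],
        }
    )
    return ItemResponseTable(df, ["x1", "x2"])


@pytest.fixture(scope="session")
def benchmark_small():
    """Fully invariant 6-group benchmark dataset with ground truth."""
    spec = invariance_benchmark_spec(G=6, n_g=800, seed=17)
    table, truth = generate(spec)
    return table, truth


def make_table(y: np.ndarray, groups, weights=None, items=None) -> ItemResponseTable:
    y = np.asarray(y, dtype=float)
    items = items or [f"x{j + 1}" for j in range(y.shape[1])]
    df = pd.DataFrame(y, columns=items)
    df.insert(0, "group", list(groups))
    df.insert(1, "weight", 1.0 if weights is None else list(weights))
    return ItemResponseTable(df, items)
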