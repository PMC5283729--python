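import numpy as np
import pandas as pd
import pytest

from metabolokit.core_data import Dataset
from metabolokit import fixtures


@pytest.fixture
def toy_dataset() -> Dataset:
    """3 features x 4 samples, two-group design, no missing values."""
    mat = pd.DataFrame(
        [[1.0, 2.0, 4.0, 8.0], [10.0, 20.0, 30.0, 40.0], [5.0, 5.0, 6.0, 7.0]],
        index=["F1", "F2", "F3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    meta = pd.DataFrame(
        {"group": ["a", "a", "b", "b"], "sample_type": ["biological"] * 4},
        index=mat.columns,
    )
    return Dataset(mat, meta)


@pytest.fixture
def toy_graph():
    return fixtures.toy_knowledge_graph()


@pytest.fixture
def null_two_group():
    """200 null Gaussian features, 20 samples per group."""
    rng = np.random.default_rng(11)
    x = rng.normal(size=(200, 20))
    y = rng.normal(size=(200, 20))
    return x, y
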