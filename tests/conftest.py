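import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from dcgnet.simulate import ExpressionStudy


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def tiny_study():
    """4 genes x 6 samples, 3 per condition, with one obvious shift in g3."""
    genes = ["g1", "g2", "g3", "g4"]
    samples = [f"n{i}" for i in range(3)] + [f"c{i}" for i in range(3)]
    values = pd.DataFrame(
        [
            [8.0, 8.1, 7.9, 8.0, 8.2, 7.8],
            [6.0, 6.2, 5.8, 6.1, 6.0, 5.9],
            [8.0, 8.1, 7.9, 11.0, 11.2, 10.8],
            [9.0, 9.1, 8.9, 9.05, 9.0, 9.1],
        ],
        index=genes,
        columns=samples,
    )
    condition = pd.Series(
        ["normal"] * 3 + ["cancer"] * 3, index=samples, name="condition"
    )
    return ExpressionStudy(values=values, condition=condition, dataset_id="tiny")


@pytest.fixture
def fixture_matrix():
    """Fixed 6-gene x 10-sample matrix for the shrinkage-lambda oracle check."""
    rng = np.random.default_rng(20240101)
    base = rng.normal(size=(6, 10))
    base[1] += 0.8 * base[0]  # induce some real correlation
    base[3] -= 0.5 * base[2]
    return np.round(base, 6)
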