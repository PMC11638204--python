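import numpy as np
import pandas as pd
import pytest

from tfkey.expr_index import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def two_gene_matrix():
    """Genes A=[8,2], B=[2,8]: equal sample totals, hand-checkable indexes."""
    frame = pd.DataFrame({"s1": [8.0, 2.0], "s2": [2.0, 8.0]},
                         index=["A", "B"])
    return ExpressionMatrix.from_frame(frame)


@pytest.fixture
def random_matrix(rng):
    """Strictly positive TPM-like matrix, 40 genes x 6 samples."""
    vals = rng.lognormal(mean=1.0, sigma=1.0, size=(40, 6))
    frame = pd.DataFrame(vals,
                         index=[f"G{i:03d}" for i in range(40)],
                         columns=[f"S{j}" for j in range(6)])
    return ExpressionMatrix.from_frame(frame)
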