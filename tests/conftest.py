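import numpy as np
import pandas as pd
import pytest

from netlnc.io_formats import GENE, LNCRNA, ExpressionMatrix, PurityVector


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_expression(values, feature_ids, sample_ids=None, lnc_prefix="L"):
    """Build an ExpressionMatrix, classifying features by id prefix."""
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=list(feature_ids), columns=list(sample_ids)),
        feature_class={
            f: (LNCRNA if f.startswith(lnc_prefix) else GENE) for f in feature_ids
        },
    )


@pytest.fixture
def small_expr():
    rng = np.random.default_rng(7)
    feats = ["L1", "L2", "G1", "G2", "G3"]
    return make_expression(rng.normal(size=(5, 30)), feats)


@pytest.fixture
def uniform_purity(small_expr):
    rng = np.random.default_rng(8)
    return PurityVector(
        values=pd.Series(rng.uniform(0.2, 0.9, size=30), index=small_expr.sample_ids)
    )
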