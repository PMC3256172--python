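import numpy as np
import pandas as pd
import pytest

from mirnapair import ExpressionMatrix, GroupDesign, TargetPair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """2 features x 3 samples, one missing value."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, np.nan, 6.0]],
        index=["feat_a", "feat_b"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(data=data, feature_kind="mRNA")


@pytest.fixture
def two_group_design():
    return GroupDesign(
        sample_to_condition={
            "r1": "healthy",
            "r2": "healthy",
            "r3": "healthy",
            "c1": "disease",
            "c2": "disease",
            "c3": "disease",
            "c4": "disease",
            "c5": "disease",
        },
        reference="healthy",
    )


@pytest.fixture
def some_pairs():
    return [
        TargetPair("mir-1", "gene-1"),
        TargetPair("mir-1", "gene-2"),
        TargetPair("mir-2", "gene-1"),
    ]
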