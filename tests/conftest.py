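import numpy as np
import pandas as pd
import pytest

from txaxes import ExpressionAtlas


@pytest.fixture
def small_atlas():
    """4 transcripts x 4 cell lines over 2 lineages, hand-set values."""
    values = pd.DataFrame(
        {
            "CL1": [8.0, 1.0, 0.0, 2.0],
            "CL2": [8.0, 1.0, 0.0, 2.0],
            "CL3": [0.0, 1.0, 0.0, 2.0],
            "CL4": [0.0, 1.0, 0.0, 2.0],
        },
        index=["tA", "tB", "tC", "tD"],
    )
    lineage = pd.Series(
        {"CL1": "lung", "CL2": "lung", "CL3": "skin", "CL4": "skin"}
    )
    return ExpressionAtlas(values, lineage)


def entropy_oracle(p):
    """Independent direct-summation Shannon entropy (base 2), 0*log2(0)=0."""
    total = 0.0
    for v in p:
        if v > 0:
            total -= v * np.log2(v)
    return total


@pytest.fixture
def specificity_oracle():
    """S_t computed by plain summation, independent of the vectorised path."""

    def score(p):
        return np.log2(len(p)) - entropy_oracle(p)

    return score
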