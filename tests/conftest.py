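import numpy as np
import pandas as pd
import pytest

from mecnet.counts import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20220959)


@pytest.fixture
def toy_table():
    """3-sample x 4-ASV table exercising both filter predicates.

    ASV_a: 1 sample only (50% there); ASV_b: 2 samples at 5%; ASV_c: 3
    samples but max 0.05%; ASV_d: 3 samples at ~30%.
    """
    counts = pd.DataFrame(
        {
            "ASV_a": [5000, 0, 0],
            "ASV_b": [0, 500, 500],
            "ASV_c": [5, 5, 5],
            "ASV_d": [4995, 9495, 9495],
        },
        index=["s1", "s2", "s3"],
    )
    return CountTable(counts)


@pytest.fixture
def random_table(rng):
    counts = rng.integers(0, 200, size=(12, 20))
    counts[rng.random(counts.shape) < 0.4] = 0
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(12)],
            columns=[f"ASV{j+1}" for j in range(20)],
        )
    )
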