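import numpy as np
import pandas as pd
import pytest

from spongenet.table import AsvTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """3 ASVs x 2 samples with known counts."""
    return AsvTable(
        pd.DataFrame(
            [[5, 0], [1, 2], [0, 7]],
            index=["asv1", "asv2", "asv3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def two_group_table():
    """5 ASVs x 6 samples: two clearly separated 3-sample groups."""
    counts = np.array(
        [
            [10, 8, 9, 1, 0, 2],
            [5, 6, 7, 0, 1, 0],
            [0, 1, 0, 9, 8, 10],
            [2, 0, 1, 6, 7, 5],
            [3, 3, 2, 3, 4, 3],
        ]
    )
    return AsvTable(
        pd.DataFrame(
            counts,
            index=list("abcde"),
            columns=[f"s{i}" for i in range(6)],
        )
    )


@pytest.fixture
def random_table(rng):
    """60 ASVs x 12 samples of lognormal-ish counts, no zeros in totals."""
    data = np.floor(rng.lognormal(1.0, 1.0, (60, 12))).astype(int)
    data[0] += 1  # guarantee nonzero sample totals
    return AsvTable(pd.DataFrame(data))
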