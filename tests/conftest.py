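import numpy as np
import pandas as pd
import pytest

import karyotempo as kt


@pytest.fixture
def three_tip_tree():
    return kt.read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry():
    return kt.read_tree("(A:1,B:1);")


@pytest.fixture
def small_counts():
    return pd.DataFrame({"species": ["A", "B", "C"], "haploid_n": [2, 3, 2]})


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
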