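import numpy as np
import pandas as pd
import pytest

from switchmodal import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    df = pd.DataFrame(
        [[0.0, 1.0, 2.0], [3.0, 4.0, 5.0]],
        index=["gA", "gB"],
        columns=["c1", "c2", "c3"],
    )
    return ExpressionMatrix({"counts": df})
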