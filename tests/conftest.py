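import numpy as np
import pandas as pd
import pytest

from xsig import ExpressionTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def small_counts():
    """3-gene x 2-sample tag-count table."""
    return ExpressionTable(
        pd.DataFrame(
            {"s1": [5, 10, 35], "s2": [1, 2, 7]},
            index=["gart", "tp53", "fbp1b"],
        ),
        "tag_count",
    )


@pytest.fixture
def random_intensity(rng):
    """100-gene x 10-sample positive intensity table."""
    data = pd.DataFrame(
        rng.uniform(1.0, 15.0, size=(100, 10)),
        index=[f"g{i:03d}" for i in range(100)],
        columns=[f"s{j}" for j in range(10)],
    )
    return ExpressionTable(data, "intensity")
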