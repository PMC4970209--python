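import numpy as np
import pandas as pd
import pytest

from anccare.ctp import DEFAULT_RANGES


@pytest.fixture
def ranges():
    return DEFAULT_RANGES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_outcome_frame(counts_by_level, var_name, outcome_name="ctp_category"):
    """Expand a {level: [n_per_outcome_category]} dict into long records."""
    from anccare.ctp import CTP_CATEGORIES

    rows = []
    for level, counts in counts_by_level.items():
        for cat, n in zip(CTP_CATEGORIES, counts):
            rows.extend({var_name: level, outcome_name: cat} for _ in range(n))
    return pd.DataFrame(rows)
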