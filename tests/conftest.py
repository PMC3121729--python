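import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def small_instance(rng, n=None, p=None):
    """Random small regression instance with a constant column."""
    n = n if n is not None else int(rng.integers(4, 13))
    p = p if p is not None else int(rng.integers(1, 4))
    n = max(n, p + 2)
    if p > 1:
        x = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    else:
        x = np.ones((n, 1))
    y = rng.normal(size=n)
    return x, y


@pytest.fixture
def refills_two_windows():
    """Fills at day 0 (90d) and day 90 (45d): windows cover days 0-135."""
    return pd.DataFrame(
        {
            "patient_id": [1, 1],
            "drug_class": ["HS501", "HS501"],
            "fill_date": ["2001-01-01", "2001-04-01"],
            "days_supplied": [90, 45],
        }
    )
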