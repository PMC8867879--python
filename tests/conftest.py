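import numpy as np
import pytest

from leadtime.lifetables import LifeTable, make_synthetic_lifetable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def constant_rate_table(rate: float, years=(1870, 2200), age_cap: int = 100) -> LifeTable:
    """Life table with (nearly) the same rate in every cell."""
    return make_synthetic_lifetable(
        a=1e-15, b=1e-9, c=rate, year_drift=1.0, years=years, age_cap=age_cap
    )


@pytest.fixture
def flat_table():
    return constant_rate_table(0.02)
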