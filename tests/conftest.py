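import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def region_df():
    """Minimal valid three-region table."""
    return pd.DataFrame({
        "region_id": ["A", "B", "C"],
        "name": ["a", "b", "c"],
        "level": ["provincial"] * 3,
        "lon": [100.0, 110.0, 120.0],
        "lat": [30.0, 35.0, 40.0],
        "life_expectancy": [72.0, 76.0, 80.0],
        "oxygen": [130.0, 150.0, 158.0],
        "gdp_per_capita": [3.0, 5.0, 8.0],
        "health_tech_per_1000": [5.0, 6.0, 7.0],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
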