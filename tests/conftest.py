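import numpy as np
import pytest

from pgccscope import SimParams, analyze_field, simulate_field


@pytest.fixture(scope="session")
def default_field_truth():
    """One simulated field at the default study conditions (90 non-PGCC,
    10 PGCC, 5 dead, 10 debris on 1024x1024 at 10x)."""
    return simulate_field(SimParams(seed=1))


@pytest.fixture(scope="session")
def default_field(default_field_truth):
    return default_field_truth[0]


@pytest.fixture(scope="session")
def default_truth(default_field_truth):
    return default_field_truth[1]


@pytest.fixture(scope="session")
def classified_records(default_field):
    """Fully classified records for the default field."""
    return analyze_field(default_field)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
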