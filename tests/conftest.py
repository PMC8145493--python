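import pytest
from hypothesis import HealthCheck, settings

from mycosynergy import load_table3, load_table4, load_table5_reference

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table3_records():
    return load_table3()


@pytest.fixture(scope="session")
def table4_4d():
    """The six mortality series at the 4-day time point, keyed by label."""
    return {s.label: s for s in load_table4(time_d=4.0)}


@pytest.fixture(scope="session")
def table5_reference():
    return load_table5_reference()
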