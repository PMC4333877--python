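import pytest
from hypothesis import HealthCheck, settings

from vaerslink import (
    SignalSpec,
    SimConfig,
    join_reports,
    simulate_dataset,
    summarize_associations,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """A small mixed dataset with one injected signal."""
    return SimConfig(
        n_reports=400,
        n_vaccines=8,
        n_symptoms=25,
        year_range=(1990, 1999),
        signals=(SignalSpec("V002", "SYM0003", 8.0),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_tables(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_collection(small_tables):
    return join_reports(small_tables)


@pytest.fixture(scope="session")
def small_summaries(small_collection):
    return summarize_associations(small_collection)


@pytest.fixture(scope="session")
def signal_dataset_5000():
    """One strong injected signal (enrichment 10) at ground-truth scale."""
    config = SimConfig(
        n_reports=5000,
        n_vaccines=10,
        n_symptoms=40,
        signals=(SignalSpec("V001", "SYM0005", 10.0),),
        seed=42,
    )
    return config, simulate_dataset(config)
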