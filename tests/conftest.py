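import pytest

from pvsignal import SimConfig, generate_dataset, load_quarters, run_analysis


@pytest.fixture(scope="session")
def small_config():
    """A small two-quarter database with two injected signals."""
    return SimConfig(
        n_background_cases=2000,
        n_target_cases=300,
        quarters=("2019Q1", "2019Q2"),
        injected_signals=[("PT_100", 5.0), ("PT_150", 5.0)],
        duplicate_rate=0.05,
        deletion_rate=0.02,
        partial_date_rate=0.10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("faers_small")
    return generate_dataset(small_config, outdir)


@pytest.fixture(scope="session")
def small_data(small_dataset):
    """Parsed quarter set plus the union of deleted lists."""
    return load_quarters(small_dataset.directory, small_dataset.quarters)


@pytest.fixture(scope="session")
def small_analysis(small_data):
    data, deleted = small_data
    return run_analysis(data, deleted)
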