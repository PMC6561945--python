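import logging

import pytest
from hypothesis import settings

import icrprofiler as icp

logging.getLogger("icrprofiler").setLevel(logging.ERROR)

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic cohort (770 genes, 8 patients, paired biopsies)."""
    return icp.generate_dataset(icp.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def normalized(default_dataset):
    counts, samples, truth = default_dataset
    expr, report = icp.normalize_pipeline(counts)
    return expr, report, samples, truth


@pytest.fixture(scope="session")
def small_config():
    """A reduced panel for simulation-heavy properties (same design, 200 genes)."""
    return icp.SyntheticConfig(seed=2, n_endogenous=200, n_signatures=6, n_categories=4)
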