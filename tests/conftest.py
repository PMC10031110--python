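import numpy as np
import pytest

from pubsem import GeneratorConfig, generate_cohort
from pubsem.preprocess import clean_hormones

TEST_SEED = 2023


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=TEST_SEED)


@pytest.fixture(scope="session")
def cohort_2000():
    """Large complete-data cohort under the default truth (no missingness or
    outliers), shared across recovery tests."""
    cfg = GeneratorConfig(n_participants=2000, missing_rates={},
                          outlier_rate=0.0, seed=TEST_SEED)
    cohort, thickness = generate_cohort(cfg)
    return cfg, cohort, thickness


@pytest.fixture(scope="session")
def clean_2000(cohort_2000):
    cfg, cohort, thickness = cohort_2000
    return cfg, clean_hormones(cohort), thickness


@pytest.fixture(scope="session")
def cohort_paper_scale(default_config):
    """Study-scale cohort (n=174) with default missingness and outliers."""
    return generate_cohort(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(TEST_SEED)
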