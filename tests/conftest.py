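"""Shared fixtures: a small seeded cohort reused across test modules."""

import numpy as np
import pytest

from chillspec import CohortConfig, fit_cspc, make_cohort
from chillspec.pipeline import derive_indicator_table


@pytest.fixture(scope="session")
def small_cohort():
    """96-record noisy cohort (4 replicates per treatment cell)."""
    config = CohortConfig(n_replicates=4, seed=11, noise_scale=0.5)
    return config, make_cohort(config)


@pytest.fixture(scope="session")
def small_indicators(small_cohort):
    _, records = small_cohort
    return derive_indicator_table(records)


@pytest.fixture(scope="session")
def small_cspc(small_indicators):
    model, result = fit_cspc(small_indicators)
    return model, result


@pytest.fixture(scope="session")
def noise_free_cohort():
    config = CohortConfig(n_replicates=1, seed=3, noise_scale=0.0)
    return config, make_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
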