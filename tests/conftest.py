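import numpy as np
import pytest

from gutshift import CohortConfig, simulate_cohort, to_relative_abundance


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared across tests (6+6 subjects not enough
    for stable recovery, so use a moderate size once per session)."""
    cfg = CohortConfig(n_per_group=27, n_features=120, n_planted_set1=10, n_planted_set2=10, seed=42)
    table, meta, truth = simulate_cohort(cfg)
    return cfg, table, meta, truth


@pytest.fixture(scope="session")
def small_comp(small_cohort):
    _, table, _, _ = small_cohort
    return to_relative_abundance(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
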