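import pandas as pd
import pytest

from mirmint.config import SimConfig
from mirmint.synthetic import (
    simulate_cohort,
    simulate_gene_sets,
    simulate_target_evidence,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but fully featured cohort configuration."""
    return SimConfig(n_mirna=60, n_mrna=300, n_gene_sets=60, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    samples, cm_mi, cm_m, truth = simulate_cohort(small_config)
    return samples, cm_mi, cm_m, truth


@pytest.fixture(scope="session")
def small_evidence(small_cohort, small_config):
    _, _, _, truth = small_cohort
    return simulate_target_evidence(truth, small_config)


@pytest.fixture(scope="session")
def small_gene_sets(small_cohort, small_config):
    _, _, _, truth = small_cohort
    return simulate_gene_sets(truth, small_config)


@pytest.fixture()
def toy_samples() -> pd.DataFrame:
    """Six samples, two per group, with covariates."""
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "group": ["nonAF", "nonAF", "parAF", "parAF", "persAF", "persAF"],
            "age": [55.0, 60.0, 65.0, 70.0, 58.0, 72.0],
            "gender": [0, 1, 0, 1, 1, 0],
        }
    )
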