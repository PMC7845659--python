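import numpy as np
import pandas as pd
import pytest

from ssripgx import phenotypes
from ssripgx.synthio import (SimulationConfig, inject_missingness,
                             simulate_genotypes, simulate_trial)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_subjects={"A": 150, "B": 100}, n_variants=40, block_size=8,
        causal_effects={"snp0005": 0.06}, seed=42)


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_trial(small_config, small_genotypes):
    subjects, panel = simulate_trial(small_genotypes, small_config)
    panel = inject_missingness(panel, small_config)
    return subjects, panel


@pytest.fixture(scope="session")
def small_phenotypes(small_trial):
    subjects, panel = small_trial
    return phenotypes.build_phenotypes(panel, subjects)


@pytest.fixture()
def null_phenotype_table():
    """Phenotype table with no genetic signal, for calibration checks."""
    def make(subject_ids, seed=0):
        rng = np.random.default_rng(seed)
        n = len(subject_ids)
        return pd.DataFrame({
            "subject_id": subject_ids,
            "pct_change": rng.normal(-0.4, 0.2, n),
            "age": rng.normal(44, 12, n),
            "sex": rng.integers(1, 3, n).astype(float),
        })
    return make
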