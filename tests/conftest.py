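import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from l1l2pheno import CohortSpec, impute_missing, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Imputed 200-sample, 300-SNP cohort with known truth (session-wide)."""
    spec = CohortSpec(
        n_families=50,
        samples_per_family=4,
        n_snps=300,
        n_chromosomes=3,
        ld_block_size=10,
        n_causal=6,
        heritability=0.5,
        seed=42,
    )
    g, ph, truth = simulate_cohort(spec)
    return impute_missing(g, seed=42), ph, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
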