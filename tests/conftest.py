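import numpy as np
import pandas as pd
import pytest

from hlagrs.genotypes import GenotypeMatrix
from hlagrs.simdata import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest clean cohort shared across tests (no contaminants)."""
    params = SimParams(n_individuals=300, n_snps=400, n_causal=10, missing_rate=0.01)
    return simulate_cohort(params, seed=7)


@pytest.fixture(scope="session")
def large_cohort():
    """A larger cohort for Monte-Carlo composition checks."""
    params = SimParams(n_individuals=20_000, n_snps=100, n_causal=20, missing_rate=0.0)
    return simulate_cohort(params, seed=11)


@pytest.fixture
def toy_genotypes():
    """Tiny handcrafted genotype matrix: 6 individuals x 4 variants."""
    dosages = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 2, 0],
            [2, 0, 1, 0],
            [0, 0, 1, 1],
            [1, 2, 0, np.nan],
            [2, 1, 0, 0],
        ],
        dtype=float,
    )
    variants = pd.DataFrame(
        {
            "id": ["v1", "v2", "v3", "v4"],
            "chrom": [1, 2, 3, 4],
            "pos": [100, 200, 300, 400],
            "a1": ["A", "C", "G", "T"],
            "a2": ["G", "T", "A", "C"],
        }
    )
    individuals = pd.DataFrame(
        {
            "iid": [f"I{k}" for k in range(6)],
            "sex": [1, 2, 1, 2, 1, 2],
            "phenotype": [1, 1, 1, 0, 0, 0],
        }
    )
    return GenotypeMatrix(dosages, variants, individuals)
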