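import numpy as np
import pandas as pd
import pytest

from gwasmodels import CASE, CONTROL, GenotypeDataset


def make_dataset(genotypes, phenotypes, is_causal=None, population_maf=None):
    """Build a GenotypeDataset from plain arrays (test helper)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_snps = genotypes.shape[1]
    if is_causal is None:
        is_causal = np.zeros(n_snps, dtype=bool)
    if population_maf is None:
        population_maf = np.full(n_snps, np.nan)
    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(n_snps)],
            "population_maf": population_maf,
            "is_causal": np.asarray(is_causal, bool),
        }
    )
    return GenotypeDataset(genotypes, np.asarray(phenotypes, np.int8), meta)


@pytest.fixture
def toy_dataset():
    """20 individuals (10 cases, 10 controls), one SNP, mixed genotypes."""
    cases = [0, 1, 2, 1, 2, 2, 0, 1, 2, 1]
    controls = [0, 0, 1, 0, 2, 1, 0, 1, 0, 0]
    genotypes = np.array(cases + controls, dtype=np.int8).reshape(-1, 1)
    phenotypes = [CASE] * 10 + [CONTROL] * 10
    return make_dataset(genotypes, phenotypes)
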