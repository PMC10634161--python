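import numpy as np
import pandas as pd
import pytest

from ifsgp import GenotypeMatrix, PhenotypeVector, SimulationConfig, simulate


def geno_from_array(dosages, chrom=None, pos=None):
    """Build a GenotypeMatrix around a raw dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    samples = pd.DataFrame(
        {"fid": [f"F{i}" for i in range(n)], "iid": [f"I{i}" for i in range(n)]}
    )
    snps = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * p,
            "snp": [f"snp{j}" for j in range(p)],
            "cm": 0.0,
            "pos": pos if pos is not None else np.arange(1, p + 1) * 10,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages, samples, snps)


def pheno(values, missing_mask=None):
    return PhenotypeVector(np.asarray(values, dtype=float), missing_mask)


@pytest.fixture(scope="session")
def strong_additive_dataset():
    """400 x 2000 dataset with 20 causal SNPs at h2 = 0.7 (fixed seed)."""
    return simulate(
        SimulationConfig(
            n_individuals=400, n_snps=2000, n_causal=20, heritability=0.7, seed=11
        )
    )


@pytest.fixture(scope="session")
def null_dataset():
    """Pure-noise phenotype: 200 x 300 with h2 = 0 (fixed seed)."""
    return simulate(
        SimulationConfig(
            n_individuals=200, n_snps=300, n_causal=0, heritability=0.0, seed=7
        )
    )
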