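import numpy as np
import pytest

from episnp import GenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_dataset(rng, n_cases=20, n_controls=20, m=10, missing_frac=0.0):
    n = n_cases + n_controls
    mafs = rng.uniform(0.1, 0.5, size=m)
    geno = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    if missing_frac:
        mask = rng.random((n, m)) < missing_frac
        geno[mask] = -1
    pheno = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return GenotypeDataset(genotypes=geno, phenotype=rng.permutation(pheno))


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng, n_cases=20, n_controls=20, m=10)


def planted_pair_dataset(rng, n_cases=100, n_controls=100, m=15, i=3, j=7):
    """Null background plus one SNP pair whose joint pattern tracks the phenotype.

    Cases are enriched for carrying a minor allele at both planted SNPs,
    creating a strong pairwise association with weak marginals left to chance.
    """
    ds = random_dataset(rng, n_cases, n_controls, m)
    case = ds.phenotype == 1
    # both-carrier genotype for most cases, both-noncarrier for most controls
    strong = rng.random(ds.n_samples) < 0.9
    for col in (i, j):
        ds.genotypes[case & strong, col] = 1 + rng.integers(
            0, 2, size=int((case & strong).sum()), dtype=np.int8
        )
        ds.genotypes[~case & strong, col] = 0
    return ds, (i, j)
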