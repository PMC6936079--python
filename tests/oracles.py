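"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's vectorised screening/threshold code
paths: patterns are built pair by pair, p-values come from the scalar table
test, and the Westfall-Young threshold is found by full enumeration with no
testability pruning.
"""

import itertools

import numpy as np

from episnp import GenotypeDataset
from episnp.encoding import encode_dataset, ktuple_pattern, pair_pattern
from episnp.significance import (
    ContingencyTable,
    chi2_pvalue,
    delta_sequence,
    estimate_fwer,
    permutation_matrix,
)


def brute_min_attainable_p(x, n1, n0):
    """Minimise the table p-value over every feasible case count a."""
    best = 1.0
    for a in range(max(0, x - n0), min(x, n1) + 1):
        best = min(best, chi2_pvalue(ContingencyTable(a, x, n1, n0)))
    return best


def all_pair_pvalues(genotypes, phenotype):
    """(pair -> (x, a, p)) for every SNP pair, encoding from the given labels."""
    ds = GenotypeDataset(genotypes=genotypes, phenotype=phenotype)
    enc = encode_dataset(ds)
    n1 = ds.n_cases
    n0 = ds.n_controls
    out = {}
    m = ds.n_snps
    for i, j in itertools.combinations(range(m), 2):
        pat = pair_pattern(enc, i, j)
        x = int(pat.sum())
        a = int(pat[np.asarray(phenotype) == 1].sum())
        out[(i, j)] = (x, a, chi2_pvalue(ContingencyTable(a, x, n1, n0)))
    return out


def naive_wy_delta_star(genotypes, phenotype, j_permutations, alpha, seed):
    """Full-enumeration Westfall-Young threshold: re-encode per permutation,
    test every pair, then take the largest non-trivial attainable delta whose
    empirical FWER stays within alpha."""
    phenotype = np.asarray(phenotype, dtype=np.int8)
    n1 = int(phenotype.sum())
    n0 = phenotype.size - n1
    perms = permutation_matrix(phenotype, j_permutations, seed)
    pmin = np.ones(j_permutations)
    for t in range(j_permutations):
        y_t = perms[:, t]
        for (x, a, p) in all_pair_pvalues(genotypes, y_t).values():
            pmin[t] = min(pmin[t], p)
    dseq = delta_sequence(n1, n0)
    feasible = [d for d in dseq[1:] if estimate_fwer(d, pmin) <= alpha]
    return (max(feasible) if feasible else float(dseq[-1])), pmin


def brute_ktuple_results(candidates, encoding, phenotype, k, delta_star_k):
    """Direct enumeration of K-subsets of the union containing a candidate pair."""
    phenotype = np.asarray(phenotype, dtype=np.int8)
    n1 = int(phenotype.sum())
    n0 = phenotype.size - n1
    pair_set = candidates.pair_index_set()
    hits = []
    for combo in itertools.combinations(candidates.snp_union, k):
        if not any(
            frozenset(p) in pair_set for p in itertools.combinations(combo, 2)
        ):
            continue
        pat = ktuple_pattern(encoding, combo)
        x = int(pat.sum())
        a = int(pat[phenotype == 1].sum())
        p = chi2_pvalue(ContingencyTable(a, x, n1, n0))
        if p <= delta_star_k:
            hits.append((combo, p))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits
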