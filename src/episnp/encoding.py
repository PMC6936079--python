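"""Case/control-ratio binarisation of genotypes and multi-locus patterns.

Each genotype class k of SNP i is recoded to a single bit from the ratio
``R_ik = (N0ik / N1ik) * (N1 / N0)``, where ``N0ik`` / ``N1ik`` count
genotype k at SNP i among controls / cases and ``N1/N0`` balances unequal
arm sizes: bit 1 iff ``R_ik > 1``.  A K-locus combination then collapses
from 3^K genotype cells to one bit per sample: 0 iff every constituent
SNP's bit is 0, else 1, giving a 2x2 phenotype-association table per
combination.

The strict ``R_ik > 1`` comparison is evaluated by integer
cross-multiplication (``N0ik * N1 > N1ik * N0``) so ties and zero counts
are exact: an empty genotype class (both counts 0) gets bit 0, a class
seen only in controls gets bit 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MISSING, GenotypeDataset

__all__ = ["BinaryEncoding", "encode_dataset", "pair_pattern", "ktuple_pattern"]


@dataclass
class BinaryEncoding:
    """Per-SNP genotype->bit maps and the resulting N x M bit matrix."""

    code_map: np.ndarray  # (M, 3) uint8, code_map[i, k] = bit of genotype k
    encoded: np.ndarray   # (N, M) uint8
    omega: float          # balance factor N1 / N0

    @property
    def n_samples(self) -> int:
        return self.encoded.shape[0]

    @property
    def n_snps(self) -> int:
        return self.encoded.shape[1]


def genotype_counts(
    genotypes: np.ndarray, phenotype: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP genotype-class counts among controls (N0ik) and cases (N1ik).

    Returns two ``(M, 3)`` integer arrays.
    """
    geno = np.asarray(genotypes)
    case = np.asarray(phenotype).astype(bool)
    counts = []
    for arm in (~case, case):
        sub = geno[arm]
        arm_counts = np.stack(
            [(sub == k).sum(axis=0) for k in range(3)], axis=1
        )
        counts.append(arm_counts.astype(np.int64))
    return counts[0], counts[1]


def encode_dataset(dataset: GenotypeDataset) -> BinaryEncoding:
    """Binarise every SNP of a complete dataset by the case/control ratio rule."""
    dataset.require_cases_and_controls()
    if (dataset.genotypes == MISSING).any():
        raise ValueError("encoding requires a complete genotype matrix; run QC first")
    n0, n1 = dataset.n_controls, dataset.n_cases
    c0, c1 = genotype_counts(dataset.genotypes, dataset.phenotype)
    # R_ik > 1  <=>  N0ik * N1 > N1ik * N0, exact in integers (handles
    # N1ik = 0: positive control count -> bit 1, empty class -> bit 0).
    code_map = (c0 * n1 > c1 * n0).astype(np.uint8)
    rows = np.arange(dataset.n_snps)
    encoded = code_map[rows[None, :], dataset.genotypes].astype(np.uint8)
    return BinaryEncoding(code_map=code_map, encoded=encoded, omega=n1 / n0)


def pair_pattern(encoding: BinaryEncoding, i: int, j: int) -> np.ndarray:
    """Binary pattern of the SNP pair (i, j): 0 iff both SNP bits are 0."""
    if i == j:
        raise ValueError("self-pairing is undefined")
    return ktuple_pattern(encoding, (i, j))


def ktuple_pattern(encoding: BinaryEncoding, snps) -> np.ndarray:
    """Binary pattern of a K-locus combination: 0 iff all K bits are 0.

    For K = 2 this is exactly ``pair_pattern``; higher orders extend the
    same rule, i.e. an elementwise OR across the encoded columns.
    """
    idx = list(snps)
    if len(idx) < 2:
        raise ValueError("a combination needs at least two SNPs")
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate SNP indices in {idx}")
    m = encoding.n_snps
    if any(not 0 <= i < m for i in idx):
        raise IndexError(f"SNP index out of range in {idx}")
    cols = encoding.encoded[:, idx]
    return (cols.max(axis=1) > 0).astype(np.uint8)
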