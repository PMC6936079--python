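"""Stage 1: screen all pairwise SNP combinations against a corrected threshold."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import BinaryEncoding
from .significance import chi2_pvalues, psi_table

__all__ = ["CandidatePair", "CandidateSet", "screen_pairs"]


@dataclass(frozen=True)
class CandidatePair:
    """A significant SNP pair with its 2x2 margins and p-value."""

    i: int
    j: int
    x: int
    a: int
    p_value: float


@dataclass
class CandidateSet:
    """Significant pairs from stage 1, sorted by p-value then (i, j)."""

    pairs: list[CandidatePair]
    delta_star: float
    snp_union: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.snp_union:
            self.snp_union = sorted({s for p in self.pairs for s in (p.i, p.j)})

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_index_set(self) -> set[frozenset[int]]:
        return {frozenset((p.i, p.j)) for p in self.pairs}

    def to_frame(self, snp_ids: list[str] | None = None) -> pd.DataFrame:
        rows = [(p.i, p.j, p.x, p.a, p.p_value) for p in self.pairs]
        df = pd.DataFrame(rows, columns=["snp_i", "snp_j", "x", "a", "p_value"])
        df["delta_star"] = self.delta_star
        if snp_ids is not None:
            df.insert(0, "snp_j_id", [snp_ids[p.j] for p in self.pairs])
            df.insert(0, "snp_i_id", [snp_ids[p.i] for p in self.pairs])
        return df


def screen_pairs(
    encoding: BinaryEncoding,
    phenotype: np.ndarray,
    delta_star: float,
    chunk_size: int = 2048,
) -> CandidateSet:
    """Test every SNP pair and keep those with p-value <= ``delta_star``.

    Pairs whose pattern margin x lies outside the testable region at
    ``delta_star`` are skipped untested: their p-value is bounded below by
    psi(x) > delta_star, so the output is identical to full enumeration.
    """
    if not 0 < delta_star <= 1:
        raise ValueError(f"delta_star={delta_star} outside (0, 1]")
    m = encoding.n_snps
    if m < 2:
        raise ValueError("need at least two SNPs to screen")
    phenotype = np.asarray(phenotype, dtype=np.int8)
    n1 = int(phenotype.sum())
    n0 = phenotype.size - n1
    psi = psi_table(n1, n0)
    y = phenotype.astype(np.float32)

    ii, jj = np.triu_indices(m, k=1)
    found: list[CandidatePair] = []
    for start in range(0, ii.size, chunk_size):
        sl = slice(start, start + chunk_size)
        pat = encoding.encoded[:, ii[sl]] | encoding.encoded[:, jj[sl]]
        x = pat.sum(axis=0).astype(np.int64)
        testable = psi[x] <= delta_star
        if not testable.any():
            continue
        pat_t = pat[:, testable].astype(np.float32)
        a = (y @ pat_t).astype(np.int64)
        xs = x[testable]
        p = chi2_pvalues(a, xs, n1, n0)
        hit = p <= delta_star
        for idx, ai, xi, pi in zip(
            np.flatnonzero(testable)[hit], a[hit], xs[hit], p[hit]
        ):
            gi = int(ii[sl][idx])
            gj = int(jj[sl][idx])
            found.append(CandidatePair(gi, gj, int(xi), int(ai), float(pi)))

    found.sort(key=lambda c: (c.p_value, c.i, c.j))
    return CandidateSet(pairs=found, delta_star=delta_star)
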