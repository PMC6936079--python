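"""Association testing with Tarone testability and permutation FWER control.

Every binarised SNP combination yields a 2x2 contingency table (pattern
value x phenotype) tested by a 1-df Pearson chi-square.  Because the table
margins are integers, a combination whose pattern is carried by ``x``
samples can never achieve a p-value below the minimum attainable value
``psi(x)``; combinations with ``psi(x)`` above the working threshold are
*untestable* and can be skipped without changing any result (Tarone's
trick).  The family-wise error rate is controlled by Westfall-Young
permutation: ``J`` phenotype permutations provide the null distribution of
the minimum p-value, and the corrected threshold is the largest attainable
value ``delta_k`` whose estimated FWER stays at or below the target.

Degenerate tables (an empty margin) are assigned p = 1 rather than NaN, and
no continuity correction is applied: the attainable-value grid and the
permutation null are computed under the identical statistic, so the
calibration is internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import chdtrc

__all__ = [
    "ContingencyTable",
    "TestableRegion",
    "TestabilityState",
    "ThresholdResult",
    "chi2_pvalue",
    "chi2_pvalues",
    "min_attainable_p",
    "psi_table",
    "delta_sequence",
    "testable_region",
    "estimate_fwer",
    "westfall_young_threshold",
    "bonferroni_threshold",
    "permutation_matrix",
]


# ---------------------------------------------------------------------------
# 2x2 chi-square
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 margins of a binary pattern against the phenotype.

    ``x`` samples carry the pattern, ``a`` of them among the ``n_cases``
    cases; the remaining cells follow from the margins.
    """

    a: int
    x: int
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        n = self.n_cases + self.n_controls
        if not (0 <= self.a <= min(self.x, self.n_cases)):
            raise ValueError(f"infeasible table: a={self.a}, x={self.x}")
        if not (0 <= self.x - self.a <= self.n_controls):
            raise ValueError(f"infeasible table: x-a={self.x - self.a}")
        if self.x > n:
            raise ValueError(f"x={self.x} exceeds N={n}")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


def _chi2_stat(a, x, n1, n0):
    """Vectorised 1-df Pearson statistic; 0 on degenerate margins."""
    a = np.asarray(a, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    n1 = float(n1)
    n0 = float(n0)
    n = n1 + n0
    denom = n1 * n0 * x * (n - x)
    det = a * (n0 - x + a) - (n1 - a) * (x - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * det * det / np.where(denom > 0, denom, 1.0), 0.0)
    return stat


def chi2_pvalues(a, x, n1: int, n0: int) -> np.ndarray:
    """Vectorised Pearson chi-square p-values for 2x2 tables (no correction)."""
    return chdtrc(1, _chi2_stat(a, x, n1, n0))


def chi2_pvalue(table: ContingencyTable) -> float:
    """P-value of one table; degenerate margins give exactly 1."""
    return float(chi2_pvalues(table.a, table.x, table.n_cases, table.n_controls))


# ---------------------------------------------------------------------------
# Minimum attainable p-values and testability
# ---------------------------------------------------------------------------

def psi_table(n1: int, n0: int) -> np.ndarray:
    """Minimum attainable p-value psi(x) for every margin x = 0..N.

    The chi-square statistic is a convex quadratic in the case count ``a``,
    so its maximum over the feasible range ``a`` in
    ``[max(0, x - N0), min(x, N1)]`` sits at an endpoint; psi(x) is the
    p-value of that extreme table.  psi is symmetric about N/2.
    """
    n = n1 + n0
    x = np.arange(n + 1)
    a_lo = np.maximum(0, x - n0)
    a_hi = np.minimum(x, n1)
    stat = np.maximum(_chi2_stat(a_lo, x, n1, n0), _chi2_stat(a_hi, x, n1, n0))
    return chdtrc(1, stat)


def min_attainable_p(x: int, n1: int, n0: int) -> float:
    """psi(x): the smallest p-value any table with margin ``x`` can reach."""
    n = n1 + n0
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    a_lo = max(0, x - n0)
    a_hi = min(x, n1)
    stat = max(float(_chi2_stat(a_lo, x, n1, n0)), float(_chi2_stat(a_hi, x, n1, n0)))
    return float(chdtrc(1, stat))


def delta_sequence(n1: int, n0: int) -> np.ndarray:
    """Distinct attainable values {delta_0=1 > delta_1 > ...}, decreasing.

    By the symmetry psi(x) = psi(N - x) only margins x <= floor(N/2) matter,
    so the sequence has at most floor(N/2) + 1 entries.
    """
    n = n1 + n0
    if n < 2:
        raise ValueError("need at least two samples")
    psi = psi_table(n1, n0)[: n // 2 + 1]
    return np.unique(psi)[::-1]


@dataclass(frozen=True)
class TestableRegion:
    """Margins x with psi(x) <= delta: [sigma_l, sigma_r] u [N-sigma_r, N-sigma_l]."""

    sigma_l: Optional[int]
    sigma_r: Optional[int]
    n: int
    _mask: np.ndarray = field(repr=False)

    def contains(self, x) -> np.ndarray:
        """Vectorised membership test for margins x."""
        return self._mask[np.asarray(x)]

    def __contains__(self, x: int) -> bool:
        return bool(self._mask[int(x)])

    @property
    def size(self) -> int:
        return int(self._mask.sum())


def testable_region(delta: float, n1: int, n0: int) -> TestableRegion:
    """The set of testable margins at level delta, Sigma(delta) = {x: psi(x) <= delta}."""
    if not 0 < delta <= 1:
        raise ValueError(f"delta={delta} outside (0, 1]")
    n = n1 + n0
    psi = psi_table(n1, n0)
    mask = psi <= delta
    half = np.flatnonzero(mask[: n // 2 + 1])
    if half.size == 0:
        return TestableRegion(sigma_l=None, sigma_r=None, n=n, _mask=mask)
    return TestableRegion(
        sigma_l=int(half[0]), sigma_r=int(half[-1]), n=n, _mask=mask
    )


def estimate_fwer(delta: float, perm_min_p: np.ndarray) -> float:
    """Westfall-Young FWER estimate: fraction of permutation minima <= delta."""
    perm_min_p = np.asarray(perm_min_p)
    if perm_min_p.size < 1:
        raise ValueError("need at least one permutation minimum")
    return float(np.mean(perm_min_p <= delta))


# ---------------------------------------------------------------------------
# Westfall-Young corrected threshold
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    """Corrected significance threshold and how it was obtained."""

    delta_star: float
    alpha: float
    method: str
    fwer_at_delta: Optional[float] = None
    warning: bool = False  # no attainable delta satisfied the FWER constraint
    j_permutations: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "delta_star": self.delta_star,
            "fwer_at_delta": self.fwer_at_delta,
            "warning": self.warning,
            "permutations": self.j_permutations,
            "seed": self.seed,
        }


@dataclass
class TestabilityState:
    """Final state of the permutation pass: delta grid, index, region, minima."""

    delta_seq: np.ndarray
    k: int
    region: TestableRegion
    perm_min_p: np.ndarray
    j_permutations: int


def permutation_matrix(phenotype: np.ndarray, j: int, seed: int) -> np.ndarray:
    """(N, J) matrix whose columns are seeded permutations of the phenotype.

    Column ``t`` is the (t+1)-th ``rng.permutation`` draw from
    ``numpy.random.default_rng(seed)``; every consumer of the same seed and
    J therefore sees the identical permutation set.
    """
    rng = np.random.default_rng(seed)
    phenotype = np.asarray(phenotype, dtype=np.int8)
    return np.stack([rng.permutation(phenotype) for _ in range(j)], axis=1)


def _encoded_bits_for_labels(
    onehot: list[np.ndarray], totals: np.ndarray, labels: np.ndarray,
    n1: int, n0: int,
) -> np.ndarray:
    """Genotype->bit maps (M, Jc, 3) for a chunk of label vectors.

    ``onehot[g]`` is the (N, M) indicator of genotype g, ``totals`` the
    (M, 3) genotype counts, ``labels`` an (N, Jc) 0/1 matrix.  The bit of
    genotype g at SNP i under label column t is 1 iff
    ``N0ig * N1 > N1ig * N0`` with the counts taken under that labelling.
    Counts are small integers, exact in float64.
    """
    c1 = np.stack(
        [onehot[g].T @ labels.astype(np.float64) for g in range(3)], axis=2
    )  # (M, Jc, 3) case counts
    c0 = totals[:, None, :] - c1
    return c0 * n1 > c1 * n0


def _gather_encoded(bits_t: np.ndarray, genotypes: np.ndarray) -> np.ndarray:
    """(N, M) bit matrix from per-SNP maps ``bits_t`` of shape (M, 3)."""
    m = genotypes.shape[1]
    return bits_t[np.arange(m)[None, :], genotypes]


def westfall_young_threshold(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    j_permutations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    combinations: Optional[np.ndarray] = None,
    perm_chunk: int = 32,
    tuple_chunk: int = 4096,
) -> tuple[ThresholdResult, TestabilityState]:
    """Westfall-Young corrected threshold over a family of SNP combinations.

    For every seeded phenotype permutation the *entire* statistic is
    recomputed — the case/control-ratio binarisation is re-derived under the
    permuted labels before the combination patterns are scored — so the
    permutation null is exchangeable with the observed analysis and the
    FWER guarantee is exact.  ``combinations=None`` tests all SNP pairs;
    otherwise a (T, K) integer array names the K-tuples to test.

    The scan starts at the largest non-trivial attainable value delta_1.
    Within each permutation, combinations whose margin x falls outside the
    current testable region are skipped: their p-value is at least
    psi(x) > delta_k, so they cannot influence the threshold.  Whenever the
    estimated FWER at delta_k exceeds ``alpha`` the index k advances and
    the region shrinks; the returned delta* = max{delta_k: FWER <= alpha}
    is identical to a full pass over every combination (Tarone pruning is a
    pure optimisation).
    """
    if j_permutations < 1:
        raise ValueError("need at least one permutation")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    genotypes = np.asarray(genotypes, dtype=np.int8)
    phenotype = np.asarray(phenotype, dtype=np.int8)
    n, m = genotypes.shape
    if combinations is None and m < 2:
        raise ValueError("need at least two SNPs")
    n1 = int(phenotype.sum())
    n0 = n - n1
    if n1 < 1 or n0 < 1:
        raise ValueError("need at least one case and one control")

    delta_seq = delta_sequence(n1, n0)
    psi = psi_table(n1, n0)
    perms = permutation_matrix(phenotype, j_permutations, seed)
    pmin = np.ones(j_permutations)

    onehot = [(genotypes == g).astype(np.float32) for g in range(3)]
    totals = np.stack([oh.sum(axis=0) for oh in onehot], axis=1)  # (M, 3)
    if combinations is None:
        iu = np.triu_indices(m, k=1)
    else:
        combinations = np.asarray(combinations, dtype=np.int64)

    k = min(1, len(delta_seq) - 1)
    for start in range(0, j_permutations, perm_chunk):
        cols = slice(start, min(start + perm_chunk, j_permutations))
        chunk = perms[:, cols]
        bits = _encoded_bits_for_labels(onehot, totals, chunk, n1, n0)
        for t in range(chunk.shape[1]):
            y_t = chunk[:, t]
            ebar = 1.0 - _gather_encoded(bits[:, t, :], genotypes).astype(
                np.float32
            )
            if combinations is None:
                gram = ebar.T @ ebar
                case = ebar[y_t == 1]
                gram_case = case.T @ case
                x = np.rint(n - gram[iu]).astype(np.int64)
                a = np.rint(n1 - gram_case[iu]).astype(np.int64)
            else:
                xs, as_ = [], []
                yf = y_t.astype(np.float32)
                for ts in range(0, combinations.shape[0], tuple_chunk):
                    sets = combinations[ts : ts + tuple_chunk]
                    pat0 = ebar[:, sets].prod(axis=2)  # 1 iff all bits 0
                    xs.append(np.rint(n - pat0.sum(axis=0)))
                    as_.append(np.rint(n1 - yf @ pat0))
                x = np.concatenate(xs).astype(np.int64)
                a = np.concatenate(as_).astype(np.int64)
            testable = psi[x] <= delta_seq[k]
            if testable.any():
                p = chi2_pvalues(a[testable], x[testable], n1, n0)
                pmin[start + t] = min(pmin[start + t], float(p.min()))
        while k + 1 < len(delta_seq) and estimate_fwer(delta_seq[k], pmin) > alpha:
            k += 1
    while k + 1 < len(delta_seq) and estimate_fwer(delta_seq[k], pmin) > alpha:
        k += 1

    fwer_k = estimate_fwer(delta_seq[k], pmin)
    warning = fwer_k > alpha  # even the smallest attainable delta fails
    result = ThresholdResult(
        delta_star=float(delta_seq[k]),
        alpha=alpha,
        method="westfall_young",
        fwer_at_delta=fwer_k,
        warning=warning,
        j_permutations=j_permutations,
        seed=seed,
    )
    state = TestabilityState(
        delta_seq=delta_seq,
        k=k,
        region=testable_region(float(delta_seq[k]), n1, n0),
        perm_min_p=pmin,
        j_permutations=j_permutations,
    )
    return result, state


def bonferroni_threshold(alpha: float, n_tests: int) -> ThresholdResult:
    """Bonferroni-corrected threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    return ThresholdResult(
        delta_star=alpha / n_tests, alpha=alpha, method="bonferroni"
    )
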