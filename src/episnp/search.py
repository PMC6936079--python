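"""Stage 2: K-locus interaction search over the stage-1 candidate set.

Small candidate sets are searched exhaustively: every K-subset of the SNPs
appearing in a candidate pair that still contains at least one whole
candidate pair is scored by the chi-square p-value of its binary K-tuple
pattern.  Large sets fall back to differential evolution (DE): each member
of the population is a real vector of K coordinates in ``[0, |union|)``;
the floor of a coordinate indexes the candidate SNP union, the fitness is
the pattern p-value, and the classic rand/1/bin scheme (mutation with
difference weight F, binomial crossover with constant CR, greedy selection
on strictly smaller p) evolves the population for ``g_max`` generations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .encoding import BinaryEncoding
from .screening import CandidateSet
from .significance import (
    ThresholdResult,
    TestabilityState,
    chi2_pvalues,
    westfall_young_threshold,
)

__all__ = [
    "DEConfig",
    "TargetVector",
    "InteractionResult",
    "ktuple_pvalue",
    "build_ktuples",
    "exhaustive_k_search",
    "threshold_for_order",
    "de_init",
    "de_mutate",
    "de_recombine",
    "de_bound",
    "de_select",
    "de_search",
]


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution settings (defaults ps=500, g=500, F=CR=0.5)."""

    ps: int = 500
    g_max: int = 500
    f: float = 0.5
    cr: float = 0.5
    k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ps < 4:
            raise ValueError("population size must be >= 4 (mutation draws 3 others)")
        if not 0.0 <= self.f <= 2.0:
            raise ValueError(f"F={self.f} outside [0, 2]")
        if not 0.0 <= self.cr <= 1.0:
            raise ValueError(f"CR={self.cr} outside [0, 1]")
        if self.k < 2:
            raise ValueError("interaction order K must be >= 2")


@dataclass(frozen=True)
class TargetVector:
    """One DE population member: real coords, decoded SNPs, fitness p-value."""

    coords: np.ndarray        # K floats in [0, upper)
    snps: tuple[int, ...]     # K distinct SNP indices (into the dataset)
    fitness_p: float


@dataclass(frozen=True)
class InteractionResult:
    """A detected K-locus interaction."""

    snps: tuple[int, ...]
    p_value: float
    significant: bool


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def _pattern_margins(
    encoding: BinaryEncoding, phenotype: np.ndarray, snp_sets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Margins (x, a) of the K-tuple patterns for rows of ``snp_sets``."""
    cols = encoding.encoded[:, snp_sets]  # (N, n_sets, K)
    pat = (cols.max(axis=2) > 0).astype(np.float32)  # (N, n_sets)
    x = pat.sum(axis=0).astype(np.int64)
    a = (np.asarray(phenotype, dtype=np.float32) @ pat).astype(np.int64)
    return x, a


def ktuple_pvalue(
    encoding: BinaryEncoding, phenotype: np.ndarray, snps: Sequence[int]
) -> float:
    """Chi-square p-value of one K-tuple's binary pattern."""
    phenotype = np.asarray(phenotype, dtype=np.int8)
    n1 = int(phenotype.sum())
    n0 = phenotype.size - n1
    x, a = _pattern_margins(encoding, phenotype, np.asarray([list(snps)]))
    return float(chi2_pvalues(a, x, n1, n0)[0])


# ---------------------------------------------------------------------------
# Exhaustive search
# ---------------------------------------------------------------------------

def build_ktuples(candidates: CandidateSet, k: int) -> list[tuple[int, ...]]:
    """All K-subsets of the candidate SNP union containing >= 1 candidate pair."""
    union = candidates.snp_union
    pair_set = candidates.pair_index_set()
    out = []
    for combo in itertools.combinations(union, k):
        if any(
            frozenset(p) in pair_set for p in itertools.combinations(combo, 2)
        ):
            out.append(combo)
    return out


def count_ktuples(candidates: CandidateSet, k: int) -> int:
    """Upper bound on the exhaustive workload: C(|union|, K)."""
    return math.comb(len(candidates.snp_union), k)


def exhaustive_k_search(
    candidates: CandidateSet,
    encoding: BinaryEncoding,
    phenotype: np.ndarray,
    k: int,
    delta_star_k: float,
) -> list[InteractionResult]:
    """Score every constructed K-tuple; report those with p <= delta_star_k."""
    if k < 3:
        raise ValueError("exhaustive K-search is for K >= 3")
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    tuples = build_ktuples(candidates, k)
    if not tuples:
        return []
    phenotype = np.asarray(phenotype, dtype=np.int8)
    n1 = int(phenotype.sum())
    n0 = phenotype.size - n1
    x, a = _pattern_margins(encoding, phenotype, np.asarray(tuples))
    p = chi2_pvalues(a, x, n1, n0)
    hits = [
        InteractionResult(snps=tuples[i], p_value=float(p[i]), significant=True)
        for i in np.flatnonzero(p <= delta_star_k)
    ]
    hits.sort(key=lambda r: (r.p_value, r.snps))
    return hits


def threshold_for_order(
    candidates: CandidateSet,
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    k: int,
    j_permutations: int,
    alpha: float,
    seed: int,
    method: str = "westfall_young",
) -> tuple[ThresholdResult, Optional[TestabilityState]]:
    """Corrected threshold for the constructed order-K pattern family.

    Reruns the same Westfall-Young machinery (same J, same seed, hence the
    same permutations) over the K-tuple combinations; the testability grid
    is unchanged because the statistic is still a 2x2 chi-square.  With
    ``method='bonferroni'`` the threshold is alpha over the family size.
    """
    tuples = build_ktuples(candidates, k)
    if not tuples:
        raise ValueError("no K-tuples can be constructed from the candidate set")
    if method == "bonferroni":
        from .significance import bonferroni_threshold

        return bonferroni_threshold(alpha, len(tuples)), None
    return westfall_young_threshold(
        genotypes, phenotype, j_permutations, alpha, seed,
        combinations=np.asarray(tuples),
    )


# ---------------------------------------------------------------------------
# Differential evolution
# ---------------------------------------------------------------------------

def _decode(coords: np.ndarray, union: Sequence[int], rng: np.random.Generator,
            upper: float) -> tuple[np.ndarray, tuple[int, ...]]:
    """Floor coords to union indices; resample duplicates until distinct.

    Bounded retries, then fill from the unused indices without replacement.
    Returns possibly-adjusted coords and the decoded SNP tuple.
    """
    coords = coords.copy()
    k = coords.size
    for _ in range(100):
        idx = np.floor(coords).astype(int)
        seen: set[int] = set()
        dup = None
        for pos in range(k):
            if idx[pos] in seen:
                dup = pos
                break
            seen.add(idx[pos])
        if dup is None:
            return coords, tuple(int(union[i]) for i in idx)
        coords[dup] = rng.random() * upper
    # fallback: deterministic fill without replacement
    idx = np.floor(coords).astype(int)
    used: set[int] = set()
    for pos in range(k):
        if idx[pos] in used:
            free = [i for i in range(len(union)) if i not in used]
            idx[pos] = int(rng.choice(free))
            coords[pos] = idx[pos] + rng.random()
        used.add(idx[pos])
    return coords, tuple(int(union[i]) for i in idx)


def _evaluate(
    coords: np.ndarray,
    union: Sequence[int],
    encoding: BinaryEncoding,
    phenotype: np.ndarray,
    rng: np.random.Generator,
    upper: float,
) -> TargetVector:
    coords, snps = _decode(coords, union, rng, upper)
    return TargetVector(
        coords=coords, snps=snps,
        fitness_p=ktuple_pvalue(encoding, phenotype, snps),
    )


def de_init(
    candidates: CandidateSet,
    config: DEConfig,
    encoding: BinaryEncoding,
    phenotype: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> list[TargetVector]:
    """Uniformly random initial population over [0, |snp union|)."""
    union = candidates.snp_union
    if len(union) < config.k:
        raise ValueError(
            f"candidate SNP union ({len(union)}) smaller than order K={config.k}"
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    upper = float(len(union))
    return [
        _evaluate(rng.random(config.k) * upper, union, encoding, phenotype,
                  rng, upper)
        for _ in range(config.ps)
    ]


def de_mutate(
    population: list[TargetVector],
    i: int,
    config: DEConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """rand/1 mutant: X_r1 + F * (X_r2 - X_r3), r1, r2, r3 distinct and != i."""
    others = [j for j in range(len(population)) if j != i]
    r1, r2, r3 = rng.choice(others, size=3, replace=False)
    return (
        population[r1].coords
        + config.f * (population[r2].coords - population[r3].coords)
    )


def de_recombine(
    target: TargetVector,
    mutant: np.ndarray,
    config: DEConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial crossover; the forced index guarantees >= 1 mutant coordinate."""
    k = target.coords.size
    forced = int(rng.integers(k))
    take = rng.random(k) <= config.cr
    take[forced] = True
    return np.where(take, mutant, target.coords)


def de_bound(
    trial: np.ndarray,
    config: DEConfig,
    target: TargetVector,
    rng: np.random.Generator,
    upper: float,
) -> np.ndarray:
    """Resample out-of-range coordinates uniformly in [0, upper)."""
    trial = trial.copy()
    bad = (trial < 0.0) | (trial >= upper)
    if bad.any():
        trial[bad] = rng.random(int(bad.sum())) * upper
    return trial


def de_select(target: TargetVector, trial: TargetVector) -> TargetVector:
    """Greedy selection: keep the trial only on strictly smaller p-value."""
    return trial if trial.fitness_p < target.fitness_p else target


def de_search(
    candidates: CandidateSet,
    encoding: BinaryEncoding,
    phenotype: np.ndarray,
    config: DEConfig,
    delta_star_k: Optional[float] = None,
    return_population: bool = False,
):
    """Run DE for ``g_max`` generations; the best vector is the detection.

    Deterministic for a fixed ``config.seed``.  When ``delta_star_k`` is
    given the result's ``significant`` flag compares against it; otherwise
    the flag is False.
    """
    rng = np.random.default_rng(config.seed)
    population = de_init(candidates, config, encoding, phenotype, rng=rng)
    union = candidates.snp_union
    upper = float(len(union))
    for _ in range(config.g_max):
        new_population = []
        for i, target in enumerate(population):
            mutant = de_mutate(population, i, config, rng)
            trial = de_recombine(target, mutant, config, rng)
            trial = de_bound(trial, config, target, rng, upper)
            trial_vec = _evaluate(trial, union, encoding, phenotype, rng, upper)
            new_population.append(de_select(target, trial_vec))
        population = new_population
    best = min(population, key=lambda v: v.fitness_p)
    result = InteractionResult(
        snps=tuple(sorted(best.snps)),
        p_value=best.fitness_p,
        significant=(delta_star_k is not None and best.fitness_p <= delta_star_k),
    )
    if return_population:
        return result, population
    return result
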