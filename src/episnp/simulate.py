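"""Penetrance-model simulation of case-control GWAS datasets.

Disease loci are drawn under Hardy-Weinberg equilibrium at a specified
minor-allele frequency and disease status is assigned from a penetrance
table over the 3^K genotype combinations of K interacting loci; rejection
sampling fills the case and control quotas.  Three parametric penetrance
families are provided, each with a baseline penetrance ``b`` (the
population prevalence for non-carriers) and one free effect parameter
``theta`` calibrated numerically so the single-locus marginal effect

    lambda = (p_Aa / p_AA) / ((1 - p_Aa) / (1 - p_AA)) - 1

hits a requested value, where ``p_AA`` and ``p_Aa`` are the marginal
penetrances of the homozygous-reference and heterozygous genotypes:

* threshold      - penetrance ``b * (1 + theta)`` iff every disease locus
                   carries at least one minor allele, else ``b``;
* multiplicative - ``b * (1 + theta) ** prod(g)`` over minor-allele counts;
* additive       - ``b * (1 + theta) ** sum(g)``.

Markers can be genotyped directly (r^2 = 1) or through a tag SNP in linkage
disequilibrium with the unobserved disease locus at a requested r^2, built
from a two-locus haplotype model with equal allele frequencies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .data import GenotypeDataset

__all__ = [
    "DiseaseModelSpec",
    "SimulationPlan",
    "MODEL_FAMILIES",
    "marginal_lambda",
    "build_model",
    "simulate_dataset",
    "simulate_null",
    "power",
]

#: model id -> (interaction order, penetrance family)
MODEL_FAMILIES: dict[str, tuple[int, str]] = {
    "model1_threshold": (2, "threshold"),
    "model2_multiplicative": (2, "multiplicative"),
    "model3_additive": (2, "additive"),
    "model4_threelocus": (3, "additive"),
    "model5_threshold3": (3, "threshold"),
}


@dataclass
class DiseaseModelSpec:
    """A penetrance table plus the population parameters that produced it."""

    order: int
    penetrance: np.ndarray          # shape (3,) * order, values in [0, 1]
    mafs: tuple[float, ...]         # per disease locus
    prevalence: float               # baseline (non-carrier) penetrance
    lam: float                      # calibrated marginal effect
    r2: float = 1.0                 # marker-locus LD; 1.0 = directly genotyped
    model_id: str = ""

    def __post_init__(self) -> None:
        self.penetrance = np.asarray(self.penetrance, dtype=float)
        if self.penetrance.shape != (3,) * self.order:
            raise ValueError(
                f"penetrance shape {self.penetrance.shape} does not match "
                f"order {self.order}"
            )
        if (self.penetrance < 0).any() or (self.penetrance > 1).any():
            raise ValueError("penetrance values must lie in [0, 1]")
        if len(self.mafs) != self.order:
            raise ValueError("one MAF per disease locus required")
        if any(not 0 < m <= 0.5 for m in self.mafs):
            raise ValueError("MAFs must lie in (0, 0.5]")
        if not 0 < self.r2 <= 1:
            raise ValueError("r2 must lie in (0, 1]")


@dataclass
class SimulationPlan:
    """Dataset sizes and the disease model for one simulation setting."""

    n_cases: int
    n_controls: int
    n_snps: int
    model: DiseaseModelSpec
    n_datasets: int = 100
    seed: int = 0
    maf_background: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("need at least one dataset")
        if self.n_snps < self.model.order:
            raise ValueError("n_snps must be >= the interaction order")


def _hwe_probs(maf: float) -> np.ndarray:
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def marginal_lambda(penetrance: np.ndarray, mafs: Sequence[float]) -> float:
    """Marginal effect of the first locus implied by a penetrance table.

    Marginal penetrances p_AA, p_Aa are obtained by averaging the table over
    the other loci with their HWE genotype weights.
    """
    penetrance = np.asarray(penetrance, dtype=float)
    order = penetrance.ndim
    table = penetrance
    for axis in range(order - 1, 0, -1):
        table = table @ _hwe_probs(mafs[axis])
    p_aa, p_het = float(table[0]), float(table[1])
    if p_aa <= 0.0 or p_aa >= 1.0:
        raise ValueError(f"marginal penetrance p_AA={p_aa} leaves lambda undefined")
    if p_het >= 1.0:
        raise ValueError("heterozygote marginal penetrance is 1")
    return (p_het / p_aa) / ((1 - p_het) / (1 - p_aa)) - 1.0


def _family_table(family: str, order: int, baseline: float, theta: float) -> np.ndarray:
    grid = np.array(list(itertools.product(range(3), repeat=order)))
    if family == "threshold":
        exponent = (grid.min(axis=1) >= 1).astype(float)
    elif family == "multiplicative":
        exponent = grid.prod(axis=1).astype(float)
    elif family == "additive":
        exponent = grid.sum(axis=1).astype(float)
    else:  # pragma: no cover - guarded by MODEL_FAMILIES
        raise ValueError(f"unknown penetrance family {family!r}")
    table = baseline * (1.0 + theta) ** exponent
    return table.reshape((3,) * order)


def build_model(
    model_id: str,
    target_lambda: float,
    maf: float,
    prevalence: float = 0.02,
    r2: float = 1.0,
) -> DiseaseModelSpec:
    """Calibrate a penetrance family so its marginal effect equals ``target_lambda``.

    The single effect parameter theta is solved by root bracketing; a
    target of 0 returns the flat (null) table.  Raises if the requested
    (lambda, MAF) combination cannot be bracketed, e.g. when the implied
    penetrance would leave [0, 1].
    """
    if model_id not in MODEL_FAMILIES:
        raise ValueError(f"unknown model_id {model_id!r}; options: {sorted(MODEL_FAMILIES)}")
    order, family = MODEL_FAMILIES[model_id]
    mafs = (maf,) * order

    def lam_of(theta: float) -> float:
        return marginal_lambda(_family_table(family, order, prevalence, theta), mafs)

    if target_lambda == 0.0:
        theta = 0.0
    else:
        # expand the bracket until the penetrance cap or a sign change
        lo = 0.0
        hi = 1.0
        max_theta = None
        while True:
            table = _family_table(family, order, prevalence, hi)
            if table.max() > 1.0:
                max_theta = hi
                break
            if lam_of(hi) >= target_lambda:
                break
            hi *= 2.0
            if hi > 1e9:
                raise ValueError(
                    f"cannot reach lambda={target_lambda} for {model_id} at "
                    f"MAF={maf}, prevalence={prevalence}"
                )
        if max_theta is not None:
            # largest theta keeping the table in [0, 1]
            hi = optimize.brentq(
                lambda t: _family_table(family, order, prevalence, t).max() - 1.0,
                lo, max_theta,
            )
            if lam_of(hi) < target_lambda:
                raise ValueError(
                    f"lambda={target_lambda} infeasible for {model_id} at "
                    f"MAF={maf}, prevalence={prevalence} (max {lam_of(hi):.4f})"
                )
        theta = optimize.brentq(
            lambda t: lam_of(t) - target_lambda, lo, hi, xtol=1e-12
        )

    table = _family_table(family, order, prevalence, theta)
    return DiseaseModelSpec(
        order=order,
        penetrance=table,
        mafs=mafs,
        prevalence=prevalence,
        lam=marginal_lambda(table, mafs) if theta > 0 else 0.0,
        r2=r2,
        model_id=model_id,
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _draw_locus_with_tag(
    rng: np.random.Generator, n: int, maf: float, r2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Disease-locus and tag-marker genotypes with allelic correlation sqrt(r2).

    Both loci share the allele frequency; per haplotype the tag allele
    matches the disease allele with the probability implied by the target
    r^2 (haplotype frequency p^2 + r * p * (1 - p) for the 1-1 haplotype).
    """
    r = math.sqrt(r2)
    disease = np.zeros(n, dtype=np.int8)
    tag = np.zeros(n, dtype=np.int8)
    for _ in range(2):  # two haplotypes per individual
        d = rng.random(n) < maf
        p_match = np.where(d, maf + r * (1 - maf), maf * (1 - r))
        t = rng.random(n) < p_match
        disease += d
        tag += t
    return disease, tag


def simulate_dataset(
    plan: SimulationPlan, seed: Optional[int] = None
) -> tuple[GenotypeDataset, dict]:
    """One case-control dataset under the plan's disease model.

    Returns the dataset and a truth record with the (column) indices of the
    disease-associated markers: the disease loci themselves at r^2 = 1,
    otherwise their tag markers (the ungenotyped loci are dropped).
    Deterministic for a given seed.
    """
    model = plan.model
    if model.penetrance.max() <= 0.0 or model.penetrance.min() >= 1.0:
        raise ValueError("penetrance admits only one phenotype class")
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    n1, n0 = plan.n_cases, plan.n_controls
    order = model.order

    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    drawn = 0
    batch = max(1024, 2 * (n1 + n0))
    while (sum(len(c) for c in case_rows) < n1
           or sum(len(c) for c in control_rows) < n0):
        if drawn > 10_000_000:
            raise RuntimeError("rejection sampling exceeded 1e7 draws")
        disease_g = np.empty((batch, order), dtype=np.int8)
        marker_g = np.empty((batch, order), dtype=np.int8)
        for loc in range(order):
            d, t = _draw_locus_with_tag(rng, batch, model.mafs[loc], model.r2)
            disease_g[:, loc] = d
            marker_g[:, loc] = t if model.r2 < 1.0 else d
        pen = model.penetrance[tuple(disease_g.T)]
        is_case = rng.random(batch) < pen
        case_rows.append(marker_g[is_case])
        control_rows.append(marker_g[~is_case])
        drawn += batch

    cases = np.concatenate(case_rows)[:n1]
    controls = np.concatenate(control_rows)[:n0]
    marker_cols = np.concatenate([cases, controls])
    phenotype = np.concatenate(
        [np.ones(n1, dtype=np.int8), np.zeros(n0, dtype=np.int8)]
    )

    n = n1 + n0
    m = plan.n_snps
    geno = np.empty((n, m), dtype=np.int8)
    background_mafs = rng.uniform(*plan.maf_background, size=m - order)
    bg = rng.binomial(2, background_mafs, size=(n, m - order)).astype(np.int8)
    disease_cols = np.sort(rng.choice(m, size=order, replace=False))
    bg_cols = np.setdiff1d(np.arange(m), disease_cols)
    geno[:, disease_cols] = marker_cols
    geno[:, bg_cols] = bg

    perm = rng.permutation(n)
    dataset = GenotypeDataset(genotypes=geno[perm], phenotype=phenotype[perm])
    truth = {
        "disease_columns": [int(c) for c in disease_cols],
        "model_id": model.model_id,
        "lambda": model.lam,
        "r2": model.r2,
        "mafs": list(model.mafs),
    }
    return dataset, truth


def simulate_null(n_cases: int, n_controls: int, n_snps: int, seed: int,
                  maf_background: tuple[float, float] = (0.05, 0.5)) -> GenotypeDataset:
    """A dataset with no genotype-phenotype association at all."""
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    mafs = rng.uniform(*maf_background, size=n_snps)
    geno = rng.binomial(2, mafs, size=(n, n_snps)).astype(np.int8)
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return GenotypeDataset(genotypes=geno, phenotype=rng.permutation(phenotype))


def power(detections: Sequence[bool]) -> float:
    """Fraction of datasets whose true interaction was reported: D' / D."""
    detections = list(detections)
    if not detections:
        raise ValueError("need at least one dataset outcome")
    return sum(bool(d) for d in detections) / len(detections)
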