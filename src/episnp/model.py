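"""User-facing model / results objects tying the two stages together.

:class:`InteractionModel` wraps a case-control genotype matrix; ``fit``
runs binarisation, corrected-threshold estimation, pairwise screening and
(optionally) the order-K search, returning an :class:`InteractionResults`
with the estimates and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import GenotypeDataset
from .encoding import BinaryEncoding, encode_dataset
from .screening import CandidateSet, screen_pairs
from .search import (
    DEConfig,
    InteractionResult,
    count_ktuples,
    de_search,
    exhaustive_k_search,
    threshold_for_order,
)
from .significance import (
    TestabilityState,
    ThresholdResult,
    bonferroni_threshold,
    westfall_young_threshold,
)

__all__ = ["InteractionModel", "InteractionResults"]


class InteractionModel:
    """Two-stage detector of SNP-SNP interactions on a case-control dataset.

    Parameters
    ----------
    genotypes
        ``(N, M)`` matrix coded by minor-allele count {0, 1, 2}; must be
        complete (run quality control first if there are missing calls).
    phenotype
        Length-``N`` 0/1 vector (1 = case).

    Examples
    --------
    >>> model = InteractionModel(genotypes, phenotype)
    >>> res = model.fit(alpha=0.05, permutations=100, seed=7)
    >>> res.candidates.to_frame()
    """

    def __init__(self, genotypes, phenotype, snp_ids=None, sample_ids=None):
        self.data = GenotypeDataset(
            genotypes=np.asarray(genotypes),
            phenotype=np.asarray(phenotype),
            snp_ids=list(snp_ids) if snp_ids is not None else [],
            sample_ids=list(sample_ids) if sample_ids is not None else [],
        )
        self.data.require_cases_and_controls()

    @classmethod
    def from_dataset(cls, dataset: GenotypeDataset) -> "InteractionModel":
        return cls(
            dataset.genotypes, dataset.phenotype,
            snp_ids=dataset.snp_ids, sample_ids=dataset.sample_ids,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, phenotype_col: str = "phenotype"
    ) -> "InteractionModel":
        """Build from a tidy frame: one row per sample, one column per SNP."""
        pheno = df[phenotype_col].to_numpy()
        geno_cols = [c for c in df.columns if c not in (phenotype_col, "sample_id")]
        sample_ids = (
            list(df["sample_id"].astype(str)) if "sample_id" in df else None
        )
        return cls(
            df[geno_cols].to_numpy(), pheno,
            snp_ids=geno_cols, sample_ids=sample_ids,
        )

    def fit(
        self,
        alpha: float = 0.05,
        permutations: int = 100,
        method: str = "westfall_young",
        order: Optional[int] = None,
        strategy: str = "auto",
        de_config: Optional[DEConfig] = None,
        seed: int = 0,
        exhaustive_limit: int = 1_000_000,
    ) -> "InteractionResults":
        """Run stage 1 (and stage 2 when ``order`` >= 3).

        ``method`` selects the multiple-testing correction: Westfall-Young
        permutation (default) or the more conservative Bonferroni variant.
        ``strategy`` chooses the order-K search: ``auto`` runs exhaustively
        when the constructed tuple count is within ``exhaustive_limit`` and
        falls back to differential evolution otherwise.
        """
        if method not in ("westfall_young", "bonferroni"):
            raise ValueError(f"unknown method {method!r}")
        if strategy not in ("auto", "exhaustive", "de"):
            raise ValueError(f"unknown strategy {strategy!r}")
        encoding = encode_dataset(self.data)
        phenotype = self.data.phenotype

        state: Optional[TestabilityState] = None
        if method == "westfall_young":
            threshold, state = westfall_young_threshold(
                self.data.genotypes, phenotype, j_permutations=permutations,
                alpha=alpha, seed=seed,
            )
        else:
            m = self.data.n_snps
            threshold = bonferroni_threshold(alpha, m * (m - 1) // 2)

        candidates = screen_pairs(encoding, phenotype, threshold.delta_star)

        order_threshold: Optional[ThresholdResult] = None
        interactions: list[InteractionResult] = []
        search_strategy_used = None
        if order is not None and order >= 3:
            if len(candidates) and len(candidates.snp_union) >= order:
                order_threshold, _ = threshold_for_order(
                    candidates, self.data.genotypes, phenotype, order,
                    j_permutations=permutations, alpha=alpha, seed=seed,
                    method=method,
                )
                use_de = strategy == "de" or (
                    strategy == "auto"
                    and count_ktuples(candidates, order) > exhaustive_limit
                )
                if use_de:
                    cfg = de_config or DEConfig(k=order, seed=seed)
                    if cfg.k != order:
                        raise ValueError("de_config.k must equal the requested order")
                    best = de_search(
                        candidates, encoding, phenotype, cfg,
                        delta_star_k=order_threshold.delta_star,
                    )
                    interactions = [best] if best.significant else []
                    search_strategy_used = "de"
                else:
                    interactions = exhaustive_k_search(
                        candidates, encoding, phenotype, order,
                        order_threshold.delta_star,
                    )
                    search_strategy_used = "exhaustive"

        return InteractionResults(
            model=self,
            encoding=encoding,
            threshold=threshold,
            state=state,
            candidates=candidates,
            order=order,
            order_threshold=order_threshold,
            interactions=interactions,
            search_strategy=search_strategy_used,
            seed=seed,
        )


@dataclass
class InteractionResults:
    """Fitted results: thresholds, candidate pairs and K-locus interactions."""

    model: InteractionModel
    encoding: BinaryEncoding
    threshold: ThresholdResult
    state: Optional[TestabilityState]
    candidates: CandidateSet
    order: Optional[int]
    order_threshold: Optional[ThresholdResult]
    interactions: list[InteractionResult] = field(default_factory=list)
    search_strategy: Optional[str] = None
    seed: int = 0

    @property
    def delta_star(self) -> float:
        return self.threshold.delta_star

    def candidates_frame(self) -> pd.DataFrame:
        return self.candidates.to_frame(self.model.data.snp_ids)

    def interactions_frame(self) -> pd.DataFrame:
        ids = self.model.data.snp_ids
        rows = [
            {
                "snps": ",".join(str(s) for s in r.snps),
                "snp_ids": ",".join(ids[s] for s in r.snps),
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in self.interactions
        ]
        return pd.DataFrame(rows, columns=["snps", "snp_ids", "p_value", "significant"])

    def to_report(self) -> dict:
        rep = {
            "n_samples": self.model.data.n_samples,
            "n_snps": self.model.data.n_snps,
            "n_cases": self.model.data.n_cases,
            "n_controls": self.model.data.n_controls,
            "threshold": self.threshold.to_dict(),
            "n_candidates": len(self.candidates),
            "seed": self.seed,
        }
        if self.order_threshold is not None:
            rep["order"] = self.order
            rep["order_threshold"] = self.order_threshold.to_dict()
            rep["search_strategy"] = self.search_strategy
            rep["interactions"] = [
                {"snps": list(r.snps), "p_value": r.p_value}
                for r in self.interactions
            ]
        return rep

    def summary(self) -> str:
        d = self.model.data
        lines = [
            "Two-stage SNP interaction screen",
            "=" * 40,
            f"samples: {d.n_samples} ({d.n_cases} cases / {d.n_controls} controls)",
            f"SNPs: {d.n_snps}",
            f"correction: {self.threshold.method}"
            + (f" (J={self.threshold.j_permutations})"
               if self.threshold.j_permutations else ""),
            f"target FWER alpha: {self.threshold.alpha}",
            f"corrected threshold delta*: {self.threshold.delta_star:.4g}",
        ]
        if self.threshold.fwer_at_delta is not None:
            lines.append(f"estimated FWER at delta*: {self.threshold.fwer_at_delta:.4g}")
        if self.threshold.warning:
            lines.append("warning: no attainable threshold satisfied the FWER target")
        lines.append(f"significant pairs: {len(self.candidates)}")
        for p in self.candidates.pairs[:10]:
            lines.append(
                f"  ({d.snp_ids[p.i]}, {d.snp_ids[p.j]})  x={p.x} a={p.a} "
                f"p={p.p_value:.3g}"
            )
        if len(self.candidates) > 10:
            lines.append(f"  ... {len(self.candidates) - 10} more")
        if self.order_threshold is not None:
            lines.append(
                f"order-{self.order} search ({self.search_strategy}), "
                f"delta*_K={self.order_threshold.delta_star:.4g}: "
                f"{len(self.interactions)} significant"
            )
            for r in self.interactions[:10]:
                ids = ", ".join(d.snp_ids[s] for s in r.snps)
                lines.append(f"  ({ids})  p={r.p_value:.3g}")
        return "\n".join(lines)
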