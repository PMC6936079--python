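# episnp

Two-stage detection of high-order SNP–SNP interactions (epistasis) in
case-control genome-wide association studies.

## The problem

Single-locus association tests explain only part of the heritability of
complex diseases; joint, non-additive effects of several loci (epistasis)
account for more. Testing them exhaustively is hard twice over: a study with
10⁶ SNPs implies ~5×10¹¹ pairs, ~1.7×10¹⁷ triples and ~8.3×10²⁷ 5-tuples of
loci, and correcting that many hypotheses with Bonferroni destroys power.

`episnp` addresses both problems with a two-stage design:

**Stage 1 — FWER-controlled pairwise screening.** Each genotype class
*k* ∈ {0,1,2} of SNP *i* is collapsed to one bit from the case/control ratio

    R_ik = (N0ik / N1ik) · (N1 / N0),   bit = 1  iff  R_ik > 1,

so a pair of SNPs becomes a single binary pattern per sample
(0 iff both bits are 0) with a 2×2 contingency table against the phenotype,
tested by a 1-df Pearson χ². The family-wise error rate over all pairs is
controlled by Westfall–Young permutation: the full statistic — binarisation
included — is recomputed under J phenotype permutations, and the corrected
threshold is

    δ* = max{ δ_k : FWER(δ_k) ≤ α },   FWER(δ) = (1/J) Σ_t 1[p_min^(t) ≤ δ],

where the grid {δ_k} contains the at most ⌊N/2⌋+1 *minimum attainable*
p-values Ψ(x) of a 2×2 table with margin x (Tarone's bound). Patterns whose
margin lies outside the testable region Σ(δ) = {x : Ψ(x) ≤ δ} are skipped —
they provably cannot reach significance — which is what makes permutation
testing affordable. A Bonferroni variant (δ* = α / #tests) is available for
comparison.

**Stage 2 — K-locus search over the candidate set.** Pairs that pass δ*
form a candidate set; K-SNP combinations built from it are scored by the χ²
p-value of their K-locus binary pattern against an order-K corrected
threshold. Small families are enumerated exhaustively; large ones are
searched by differential evolution (rand/1/bin: mutation
V = X_r1 + F·(X_r2 − X_r3), binomial crossover with constant CR, greedy
selection on the p-value), with real coordinates decoded to candidate SNP
indices.

A penetrance-model simulator (threshold, multiplicative and additive
two-locus families plus three-locus analogues, calibrated to a requested
marginal effect λ, with optional tag markers in LD r² with unobserved
disease loci) supports power and error studies; see `docs/methods.md`.

## Worked example

```python
from episnp import InteractionModel, SimulationPlan, build_model, simulate_dataset

spec = build_model("model1_threshold", target_lambda=0.5, maf=0.2)
plan = SimulationPlan(n_cases=1000, n_controls=1000, n_snps=100, model=spec)
dataset, truth = simulate_dataset(plan, seed=7)
print("disease columns:", truth["disease_columns"])

model = InteractionModel.from_dataset(dataset)
results = model.fit(alpha=0.05, permutations=100, seed=7)
print(results.summary())
```

prints

```
disease columns: [36, 86]
Two-stage SNP interaction screen
========================================
samples: 2000 (1000 cases / 1000 controls)
SNPs: 100
correction: westfall_young (J=100)
target FWER alpha: 0.05
corrected threshold delta*: 2.4e-06
estimated FWER at delta*: 0.04
significant pairs: 1
  (snp36, snp86)  x=1652 a=775 p=1.79e-09
```

The simulator planted a two-locus threshold interaction (marginal effect
λ = 0.5, MAF 0.2) at columns 36 and 86. The permutation pass set the
corrected threshold δ* = 2.4×10⁻⁶ — the largest attainable p-value whose
estimated FWER (here 0.04) stays within the α = 0.05 target — and exactly
one pair survives it: the planted one. `x` is the number of samples whose
joint binary pattern is 1 and `a` the number of those that are cases; the
pair's χ² p-value of 1.8×10⁻⁹ is far below δ*. Passing `order=3` to
`fit()` additionally runs the stage-2 search and reports significant
three-locus combinations.

The same analysis is available from the shell:

```sh
episnp simulate --model model1 --lambda 0.5 --maf 0.2 --cases 1000 \
    --controls 1000 --snps 100 --datasets 1 --seed 7 --outdir sim/
episnp run --in sim/dataset_000.tsv --outdir out/ --permutations 100 --seed 7
```

Subcommands: `qc`, `encode`, `screen`, `search`, `simulate`, `power`, `run`.

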