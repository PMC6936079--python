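# Methods

This note documents the statistical machinery implemented in `episnp`, the
choices made where the design was genuinely open, and what the simulator
does and does not emulate.

## Binarisation of genotypes and combinations

Genotypes are coded by minor-allele count {0, 1, 2}. For SNP *i* and
genotype class *k*, with `N1ik` / `N0ik` the class counts among cases /
controls and ω = N1/N0 the arm-size balance factor, the class is encoded as
bit 1 iff R_ik = (N0ik/N1ik)·ω > 1. A K-locus combination is then the
sample-wise OR of its K SNP bits: 0 iff every bit is 0. This collapses the
3^K genotype table to a 2×2 table (pattern × phenotype) at the cost of
genetic resolution — a deliberate trade; see Limitations.

Numerical choices:

* The strict `R > 1` comparison is evaluated by integer cross-multiplication
  (`N0ik·N1 > N1ik·N0`), so ties are exact and no floating-point division
  occurs. An exact tie takes the "otherwise" branch (bit 0).
* Zero counts need no special casing under cross-multiplication: a class
  seen only in controls gets bit 1 (the ratio is effectively infinite), an
  absent class gets bit 0 (no evidence).
* For K ≥ 3 the same "0 iff all bits 0" rule is used. This is an
  interpretation: the two-locus rule generalises in more than one way, and
  we chose the one that keeps the 2×2 testing machinery (including Ψ(x) and
  the testable regions) valid at every order.

## Association test

Each pattern is tested by the 1-df Pearson χ² on the 2×2 table with margins
(x, a): x samples carry the pattern, a of them cases. No Yates continuity
correction and no minimum-expected-count rule are applied: the attainable
p-value grid and the permutation null are computed under the identical
statistic, so the calibration is internal and any systematic bias of the raw
statistic cancels. Degenerate tables (x = 0, x = N, or an empty arm) are
assigned p = 1 rather than NaN so they can never appear significant.

## Minimum attainable p-values and testable regions

For fixed margins, the χ² statistic is a convex quadratic in the case count
a, so its maximum over the feasible range a ∈ [max(0, x−N0), min(x, N1)]
is attained at an endpoint; Ψ(x), the smallest p-value any table with
margin x can reach, is evaluated from the two endpoints only (the tests
verify this against brute-force minimisation). Ψ is symmetric about N/2,
giving at most ⌊N/2⌋+1 distinct values δ_0 = 1 > δ_1 > … — the only
thresholds at which anything can change.

The testable region Σ(δ) = {x : Ψ(x) ≤ δ} is materialised by a direct scan
of the Ψ table (O(N) per level) rather than an incremental interval update;
the two representations are definitionally equal, and the scan keeps the
region exact even if Ψ were not unimodal for some unbalanced split. The
stored σ_l/σ_r interval bounds are derived from the scan.

## Westfall–Young threshold with Tarone pruning

J permutations of the phenotype are drawn once from a seeded generator and
shared by every consumer (the pair family and any order-K family rerun with
the same seed see identical permutations). For each permutation the **whole
statistic is recomputed, including the binarisation**: the genotype→bit maps
are re-derived from the permuted case/control counts before patterns are
scored. This matters: the encoding is selected using the observed labels, so
permuting labels under fixed patterns would compare a selection-biased
observed statistic against an unbiased null and inflate the error rate.
Re-encoding restores exchangeability and makes the FWER guarantee exact;
the acceptance suite measures the empirical FWER on null data.

The scan starts at δ_1 (δ_0 = 1 is never a usable threshold). Within a
permutation, combinations with Ψ(x) above the current δ_k are skipped —
their p-value cannot reach any smaller δ — and whenever the estimated FWER
at δ_k exceeds α the index advances, shrinking the region for all later
work. Because skipped combinations are provably irrelevant below δ_k, the
final δ* = max{δ_k : FWER(δ_k) ≤ α} is identical to a full enumeration; a
brute-force oracle asserts this equality in the tests. If even the smallest
attainable δ fails the constraint, that δ is returned with a warning flag
(nothing can be called significant at it). Counts are accumulated through
float32 matrix products (exact for the integer magnitudes involved) and
rounded back to integers.

The Bonferroni variant divides α by the family size; it is retained as the
more conservative baseline.

## Stage 2: exhaustive and differential-evolution search

The candidate set is the list of pairs with p ≤ δ*, and its SNP union
(sorted distinct members) defines the stage-2 space. Exhaustive search
scores every K-subset of the union that still contains at least one whole
candidate pair — our reading of "combining candidate pairs to K-sets";
requiring a contained pair keeps the family anchored to stage-1 evidence.
The order-K threshold is obtained by rerunning the Westfall–Young machinery
over exactly that family with the same seed and J.

Differential evolution (rand/1/bin) is the fallback for large sets
(default cutoff: 10⁶ constructed tuples). Each population member carries K
real coordinates in [0, |union|); the floor of a coordinate indexes the
union. Defaults ps = 500, g_max = 500, F = 0.5, CR = 0.5; the acceptance
test uses ps = 50, g = 100 on a set small enough to enumerate. Choices the
scheme itself leaves open:

* Out-of-range trial coordinates are resampled uniformly in range;
  in-range trial coordinates are kept (reverting them to the target's
  coordinate would partially undo crossover).
* Two coordinates flooring to the same SNP are repaired by resampling the
  later coordinate (bounded retries, then a draw without replacement), so
  every evaluated vector names K distinct SNPs.
* Selection is strictly greedy on the p-value; ties keep the incumbent.
* The single best vector is reported (with the final population available
  on request); its significance is judged against the order-K threshold.

## Simulator

Disease loci are drawn under Hardy–Weinberg equilibrium at the requested
MAF; disease status follows a penetrance table over the 3^K genotype
combinations; rejection sampling fills the case and control quotas
(capped at 10⁷ draws). Three parametric families are provided, each with
baseline penetrance b and one effect parameter θ:

| family         | penetrance                                   |
|----------------|----------------------------------------------|
| threshold      | b·(1+θ) iff every locus carries ≥1 minor allele, else b |
| multiplicative | b·(1+θ)^(∏ g_i)                              |
| additive       | b·(1+θ)^(Σ g_i)                              |

`model1`–`model3` are the two-locus threshold / multiplicative / additive
families; `model4` and `model5` are the three-locus additive and threshold
analogues. θ is solved by root bracketing so the single-locus marginal
effect λ = (p_Aa/p_AA)/((1−p_Aa)/(1−p_AA)) − 1 — marginal penetrances taken
by HWE-weighted averaging over the other loci — hits the requested value;
infeasible (λ, MAF, b) combinations raise with the attainable maximum named.
The three-locus `model4` uses the additive family because a three-locus
product exponent saturates the penetrance cap at marginal effects an order
of magnitude below the study settings.

Parameter defaults and why:

* **b (prevalence) = 0.02.** The baseline must be small enough that the
  largest penetrance cell stays ≤ 1 across the λ ∈ {0.1, 0.2, 0.3} ×
  MAF ∈ {0.1, 0.2, 0.4} calibration grid for every family; 0.02 is a
  realistic complex-disease prevalence satisfying that with headroom.
* **Background SNPs**: independent of phenotype, MAF uniform on
  [0.05, 0.5] (post-QC frequencies in real panels occupy roughly this
  range). Disease markers are placed at seeded random columns; the truth
  record names them.
* **LD tags**: for r² < 1 the disease locus is unobserved and a tag marker
  with the same allele frequency is genotyped instead; per haplotype the
  tag allele matches the disease allele with the probability implied by
  allelic correlation r = √r², the simplest two-locus haplotype model
  meeting the r² constraint. The truth record then names the tag columns,
  since they are what a detector can possibly find.

What the simulator does **not** emulate: genotyping error and missingness
(QC is exercised on synthetically degraded data in the tests instead),
population stratification, linkage between background markers, sex
chromosomes, and covariates. Passing tests therefore demonstrate the
statistical machinery under idealised sampling, not robustness to the
artefacts of real genotype data.

## Quality control

Samples are filtered first (call rate < 98% by default), then SNPs over the
retained samples: call rate < 95%, Hardy–Weinberg 1-df χ² goodness-of-fit
p-value in controls < 10⁻⁴, or MAF < 0.1. Comparisons are strict, so
boundary values pass. MAF is computed over all retained samples; call-rate
denominators count attempted genotypes. Downstream stages need a complete
matrix, so remaining missing calls are median-imputed per SNP (overridable);
the report logs every removal with its reason and the imputed-call count.

## Problem sizes used in the checks

The statistical acceptance tests run at desk scale: 100 null datasets of
200 samples × 50 SNPs for the FWER check; 100 replicates of 2000 samples ×
100 SNPs with a planted threshold-model interaction (λ = 0.5, MAF 0.2) for
end-to-end recovery, an effect strong enough that a correct implementation
should rarely miss it; Ψ/region oracles exhaustively up to N = 200; DE
against exhaustive enumeration on a ~40-SNP union. These sizes exercise
every code path of the genome-scale machinery while keeping the suite
runnable in minutes.

## Known limitations

* Collapsing genotype combinations to one bit loses genetic information;
  interactions whose signal lives in a partition finer than
  "both-reference vs anything else" lose power by construction.
* Main effects are not conditioned out: a strong single-locus effect makes
  many pairs containing that locus significant, inflating the candidate set
  (visible in the stage-2 family sizes on strong-effect simulations).
* Permutation testing with full re-encoding costs J times the single-pass
  work; Tarone pruning reduces but does not remove this.
* The screening stage enumerates all C(M, 2) pairs in memory-friendly
  chunks but is designed for desk-scale M (10²–10⁴), not full genome-wide
  panels.
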