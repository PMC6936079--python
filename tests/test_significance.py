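import numpy as np
import pytest

from episnp import (
    ContingencyTable,
    bonferroni_threshold,
    chi2_pvalue,
    delta_sequence,
    estimate_fwer,
    min_attainable_p,
    westfall_young_threshold,
)
from episnp.significance import testable_region as region_at
from episnp.significance import psi_table

from conftest import random_dataset
from oracles import brute_min_attainable_p, naive_wy_delta_star


class TestChi2:
    def test_hand_computed_balanced_table(self):
        # a=30, x=50, N1=N0=50: all expected cells 25, chi2 = 4.0
        p = chi2_pvalue(ContingencyTable(a=30, x=50, n_cases=50, n_controls=50))
        assert p == pytest.approx(0.04550026, abs=1e-7)

    def test_independence_gives_p_one(self):
        # a = x * N1 / N exactly
        p = chi2_pvalue(ContingencyTable(a=10, x=20, n_cases=30, n_controls=30))
        assert p == pytest.approx(1.0)

    def test_degenerate_margins_give_p_one(self):
        assert chi2_pvalue(ContingencyTable(0, 0, 25, 35)) == 1.0
        assert chi2_pvalue(ContingencyTable(25, 60, 25, 35)) == 1.0

    def test_infeasible_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=5, x=4, n_cases=10, n_controls=10)
        with pytest.raises(ValueError):
            ContingencyTable(a=0, x=30, n_cases=10, n_controls=10)


class TestMinAttainableP:
    def test_trivial_value_at_zero_margin(self):
        assert min_attainable_p(0, 50, 50) == 1.0

    def test_single_carrier_balanced(self):
        # x=1, N1=N0=50: extreme table has chi2 = 100/99, p ~ 0.3149
        assert min_attainable_p(1, 50, 50) == pytest.approx(
            brute_min_attainable_p(1, 50, 50), abs=1e-12
        )
        assert min_attainable_p(1, 50, 50) == pytest.approx(0.31488, abs=1e-4)

    @pytest.mark.parametrize("n1,n0", [(17, 20), (5, 32), (18, 19)])
    def test_symmetry_about_half(self, n1, n0):
        n = n1 + n0
        for x in range(n + 1):
            assert min_attainable_p(x, n1, n0) == pytest.approx(
                min_attainable_p(n - x, n1, n0), abs=1e-12
            )

    def test_matches_brute_force_small(self):
        for n1, n0 in [(6, 6), (4, 9), (10, 3)]:
            for x in range(n1 + n0 + 1):
                assert min_attainable_p(x, n1, n0) == pytest.approx(
                    brute_min_attainable_p(x, n1, n0), abs=1e-12
                )

    def test_lower_bounds_every_feasible_table(self):
        n1, n0 = 8, 11
        for x in range(n1 + n0 + 1):
            psi = min_attainable_p(x, n1, n0)
            for a in range(max(0, x - n0), min(x, n1) + 1):
                assert chi2_pvalue(ContingencyTable(a, x, n1, n0)) >= psi - 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            min_attainable_p(25, 10, 10)


class TestDeltaSequence:
    def test_count_bound_and_monotonicity(self):
        seq = delta_sequence(5, 5)
        assert seq[0] == 1.0
        assert len(seq) <= 10 // 2 + 1
        assert np.all(np.diff(seq) < 0)

    def test_balanced_minimum_at_half(self):
        n1 = n0 = 12
        seq = delta_sequence(n1, n0)
        assert seq[-1] == pytest.approx(min_attainable_p(12, n1, n0))
        brute = min(min_attainable_p(x, n1, n0) for x in range(25))
        assert seq[-1] == pytest.approx(brute)


class TestTestableRegion:
    def test_trivial_delta_covers_everything(self):
        region = region_at(1.0, 20, 25)
        assert region.sigma_l == 0
        assert all(x in region for x in range(46))

    def test_matches_brute_force_set(self):
        n1, n0 = 20, 40
        psi = psi_table(n1, n0)
        region = region_at(0.01, n1, n0)
        for x in range(n1 + n0 + 1):
            assert (x in region) == (psi[x] <= 0.01)

    def test_nested_in_delta(self):
        n1, n0 = 15, 22
        seq = delta_sequence(n1, n0)
        prev = set(range(n1 + n0 + 1))
        for d in seq:
            cur = {x for x in range(n1 + n0 + 1) if x in region_at(d, n1, n0)}
            assert cur <= prev
            prev = cur


class TestEstimateFwer:
    def test_direct_count(self):
        assert estimate_fwer(0.5, np.array([0.2, 0.6, 0.9])) == pytest.approx(1 / 3)

    def test_extremes(self):
        p = np.array([0.1, 0.4, 0.7])
        assert estimate_fwer(0.7, p) == 1.0
        assert estimate_fwer(0.05, p) == 0.0

    def test_monotone_in_delta(self, rng):
        p = rng.uniform(size=50)
        fw = [estimate_fwer(d, p) for d in np.linspace(0, 1, 21)]
        assert all(b >= a for a, b in zip(fw, fw[1:]))


class TestWestfallYoung:
    def test_matches_naive_oracle(self, rng):
        for _ in range(3):
            ds = random_dataset(rng, n_cases=15, n_controls=15, m=8)
            seed = int(rng.integers(2**31))
            res, state = westfall_young_threshold(
                ds.genotypes, ds.phenotype, j_permutations=30, alpha=0.05,
                seed=seed,
            )
            oracle, pmin = naive_wy_delta_star(
                ds.genotypes, ds.phenotype, 30, 0.05, seed
            )
            assert res.delta_star == pytest.approx(oracle, rel=1e-12)

    def test_alpha_one_returns_largest_nontrivial(self, rng):
        ds = random_dataset(rng, n_cases=10, n_controls=10, m=5)
        res, state = westfall_young_threshold(
            ds.genotypes, ds.phenotype, j_permutations=10, alpha=1.0, seed=3
        )
        seq = delta_sequence(10, 10)
        assert res.delta_star == pytest.approx(seq[1])

    def test_snp_order_invariance(self, rng):
        ds = random_dataset(rng, n_cases=12, n_controls=14, m=7)
        res1, _ = westfall_young_threshold(
            ds.genotypes, ds.phenotype, j_permutations=25, alpha=0.1, seed=11
        )
        perm = rng.permutation(7)
        res2, _ = westfall_young_threshold(
            ds.genotypes[:, perm], ds.phenotype, j_permutations=25, alpha=0.1,
            seed=11,
        )
        assert res1.delta_star == pytest.approx(res2.delta_star)

    def test_fwer_constraint_holds_unless_flagged(self, rng):
        ds = random_dataset(rng, n_cases=20, n_controls=20, m=10)
        res, state = westfall_young_threshold(
            ds.genotypes, ds.phenotype, j_permutations=40, alpha=0.05, seed=5
        )
        if not res.warning:
            assert res.fwer_at_delta <= 0.05
        assert estimate_fwer(res.delta_star, state.perm_min_p) == pytest.approx(
            res.fwer_at_delta
        )

    def test_deterministic_per_seed(self, rng):
        ds = random_dataset(rng, n_cases=12, n_controls=12, m=6)
        a = westfall_young_threshold(ds.genotypes, ds.phenotype, 20, 0.05, seed=9)
        b = westfall_young_threshold(ds.genotypes, ds.phenotype, 20, 0.05, seed=9)
        assert a[0].delta_star == b[0].delta_star
        np.testing.assert_array_equal(a[1].perm_min_p, b[1].perm_min_p)


class TestBonferroni:
    def test_pair_count_example(self):
        res = bonferroni_threshold(0.05, 100 * 99 // 2)
        assert res.delta_star == pytest.approx(1.0101e-5, rel=1e-3)
        assert res.method == "bonferroni"

    def test_single_test_identity_and_bound(self):
        assert bonferroni_threshold(0.05, 1).delta_star == 0.05
        for n in (1, 10, 12345):
            assert bonferroni_threshold(0.05, n).delta_star <= 0.05
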