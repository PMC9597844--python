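"""Differentiation estimators and significance tests."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln

from msatpop.differentiation import (
    bootstrap_ci,
    chi2_genic_test,
    differentiation,
    exact_genic_test,
    fisher_combine,
    genic_table,
    genic_test_global,
    gst_from_frequencies,
    hedrick_gprime_st,
    mc_exact_from_table,
    narum_adjust,
    pairwise_differentiation,
    wc_theta,
)
from msatpop.synthetic import generate_null_metapopulation

from conftest import dataset_from_calls


class TestWcTheta:
    def test_hand_computed_two_population_case(self, toy_two_pops):
        res = wc_theta(toy_two_pops)
        assert res.theta == pytest.approx(0.515152, abs=1e-6)

    def test_fixed_difference_gives_one(self, fixed_difference):
        assert wc_theta(fixed_difference).theta == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        inds = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]]
        ds = dataset_from_calls({"a": inds, "b": inds})
        assert wc_theta(ds).theta <= 0.0

    def test_single_population_errors(self):
        ds = dataset_from_calls({"a": [[(1, 2)], [(1, 1)]]})
        with pytest.raises(ValueError):
            wc_theta(ds)

    def test_multilocus_is_ratio_of_sums(self):
        """Multilocus theta != mean of per-locus ratios on an uneven fixture."""
        ds = dataset_from_calls({
            "a": [[(1, 1), (1, 2)], [(1, 1), (1, 1)], [(1, 2), (1, 2)],
                  [(1, 2), (2, 2)]],
            "b": [[(2, 2), (1, 2)], [(2, 2), (1, 1)], [(1, 2), (2, 2)],
                  [(2, 2), (1, 2)]],
        })
        res = wc_theta(ds)
        per_locus = list(res.theta_per_locus.values())
        assert res.theta != pytest.approx(np.mean(per_locus), abs=1e-6)
        # rebuild the ratio-of-sums from single-locus components
        from msatpop.differentiation import _wc_components_locus
        comps = [_wc_components_locus(ds, l, ds.populations) for l in ds.loci]
        num = sum(c[0] for c in comps)
        den = sum(sum(c) for c in comps)
        assert res.theta == pytest.approx(num / den, abs=1e-12)


class TestGStatistics:
    def test_hand_computed_case(self):
        res = gst_from_frequencies(np.array([[0.75, 0.25], [0.125, 0.875]]))
        assert res.hs == pytest.approx(0.296875, abs=1e-9)
        assert res.ht == pytest.approx(0.4921875, abs=1e-9)
        assert res.gst == pytest.approx(0.396825, abs=1e-6)
        assert res.gprime_st == pytest.approx(0.731922, abs=1e-6)

    def test_fixed_difference_reaches_one(self):
        res = gst_from_frequencies(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert res.gprime_st == pytest.approx(1.0)

    def test_identical_frequencies_zero(self):
        res = gst_from_frequencies(np.array([[0.3, 0.7], [0.3, 0.7]]))
        assert res.gst == pytest.approx(0.0, abs=1e-12)
        assert res.gprime_st == pytest.approx(0.0, abs=1e-12)

    def test_all_fixed_same_allele_undefined(self):
        res = gst_from_frequencies(np.array([[1.0], [1.0]]))
        assert math.isnan(res.gst)

    def test_gprime_magnitude_dominates_gst(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            p = rng.dirichlet(np.ones(4), size=3)
            res = gst_from_frequencies(p)
            if res.hs > 0 and not math.isnan(res.gprime_st):
                assert abs(res.gprime_st) >= abs(res.gst) - 1e-12

    def test_multilocus_averages_hs_ht(self):
        mats = [np.array([[0.75, 0.25], [0.125, 0.875]]),
                np.array([[0.5, 0.5], [0.5, 0.5]])]
        res = hedrick_gprime_st(mats)
        assert res.hs == pytest.approx((0.296875 + 0.5) / 2)
        assert res.ht == pytest.approx((0.4921875 + 0.5) / 2)

    def test_dataset_level_fixed_difference(self, fixed_difference):
        res = differentiation(fixed_difference)
        assert res.gprime_st == pytest.approx(1.0, abs=1e-9)
        assert res.theta == pytest.approx(1.0, abs=1e-9)


class TestBootstrap:
    def test_degenerate_identical_individuals_zero_width(self):
        ds = dataset_from_calls({
            "a": [[(1, 2)]] * 5, "b": [[(1, 2)]] * 5,
        })
        lo, hi = bootstrap_ci(ds, "theta", reps=200, seed=1)
        assert lo == hi

    def test_fixed_difference_ci_is_degenerate_at_one(self, fixed_difference):
        lo, hi = bootstrap_ci(fixed_difference, "theta", reps=200, seed=1)
        assert (lo, hi) == (1.0, 1.0)

    def test_single_individual_population_errors(self):
        ds = dataset_from_calls({"a": [[(1, 2)]], "b": [[(1, 1)], [(2, 2)]]})
        with pytest.raises(ValueError):
            bootstrap_ci(ds, reps=100)

    def test_reps_floor(self, fixed_difference):
        with pytest.raises(ValueError):
            bootstrap_ci(fixed_difference, reps=10)

    def test_null_ci_spans_zero(self, baseline):
        """Panmictic pseudo-populations: the theta CI should cover 0 mostly."""
        covered = 0
        n_runs = 30
        for r in range(n_runs):
            ds = generate_null_metapopulation(baseline, 14, 10, seed=(777, r))
            lo, hi = bootstrap_ci(ds, "theta", reps=200, seed=r)
            covered += lo <= 0.0 <= hi
        # >= 90% coverage claimed; 25/30 keeps the false-alarm rate tiny
        assert covered >= 25


def _enumeration_p_2xc(table: np.ndarray) -> float:
    """Exact conditional p over all 2-row tables with fixed margins."""
    table = np.asarray(table, dtype=np.int64)
    row, col = table.sum(axis=1), table.sum(axis=0)

    def log_prob(t):
        return (gammaln(row + 1).sum() + gammaln(col + 1).sum()
                - gammaln(row.sum() + 1) - gammaln(t + 1).sum())

    obs = log_prob(table)
    total = 0.0
    hit = 0.0
    ranges = [range(0, min(row[0], c) + 1) for c in col]
    for combo in itertools.product(*ranges):
        if sum(combo) != row[0]:
            continue
        t = np.vstack([np.array(combo), col - np.array(combo)])
        if (t < 0).any():
            continue
        lp = log_prob(t)
        p = math.exp(lp)
        total += p
        if lp <= obs + 1e-9:
            hit += p
    assert abs(total - 1.0) < 1e-9
    return hit


class TestExactGenicTest:
    def test_mc_matches_enumeration(self):
        table = np.array([[6, 2], [2, 6]])
        exact = _enumeration_p_2xc(table)
        reps = 20_000
        p_mc = mc_exact_from_table(table, reps=reps, seed=2)
        se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(p_mc - exact) < 3 * se + 1 / reps

    @pytest.mark.parametrize("seed", range(4))
    def test_mc_matches_enumeration_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 5, size=(2, rng.integers(2, 4)))
        table[0, 0] += 2
        table[1, -1] += 2
        exact = _enumeration_p_2xc(table)
        p_mc = mc_exact_from_table(table, reps=20_000, seed=seed + 10)
        se = math.sqrt(max(exact * (1 - exact), 1e-6) / 20_000)
        assert abs(p_mc - exact) < 4 * se + 1e-4

    def test_identical_counts_large_p(self):
        ds = dataset_from_calls({
            "a": [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]],
            "b": [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]],
        })
        assert exact_genic_test(ds, "L1", mc_reps=2000, seed=3) >= 0.5

    def test_disjoint_allele_sets_tiny_p(self):
        ds = dataset_from_calls({
            "a": [[(1, 1)]] * 10, "b": [[(2, 2)]] * 10,
        })
        assert exact_genic_test(ds, "L1", mc_reps=100_000, seed=4) <= 0.001

    def test_p_never_zero(self):
        table = np.array([[20, 0], [0, 20]])
        p = mc_exact_from_table(table, reps=1000, seed=5)
        assert p >= 1 / 1001

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            mc_exact_from_table(np.empty((0, 0)))


class TestFisherCombine:
    def test_all_ones(self):
        chi2, df, p = fisher_combine([1.0, 1.0, 1.0])
        assert chi2 == 0.0 and df == 6 and p == pytest.approx(1.0)

    def test_hand_case(self):
        chi2, df, p = fisher_combine([0.05, 0.5])
        assert chi2 == pytest.approx(7.37776, abs=1e-5)
        assert df == 4
        # closed-form chi-square df=4 upper tail: e^{-x/2}(1 + x/2)
        closed = math.exp(-chi2 / 2) * (1 + chi2 / 2)
        assert p == pytest.approx(closed, abs=1e-12)

    def test_floor_applied(self):
        chi2_f, _, _ = fisher_combine([1e-8, 0.5])
        chi2_ref, _, _ = fisher_combine([1e-4, 0.5])
        assert chi2_f == pytest.approx(chi2_ref, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            fisher_combine([])
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


class TestNarum:
    def test_values(self):
        assert narum_adjust(0.05, 1) == pytest.approx(0.05)
        assert narum_adjust(0.05, 91) == pytest.approx(0.009816, abs=1e-6)

    def test_strictly_decreasing(self):
        vals = [narum_adjust(0.05, k) for k in range(1, 40)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        with pytest.raises(ValueError):
            narum_adjust(0.05, 0)


class TestGlobalAndPairwise:
    def test_chi2_sums_over_loci(self, fixed_difference):
        res = genic_test_global(fixed_difference, method="chi2")
        assert res.p_global < 1e-4
        assert res.df == 1  # one locus, 2 alleles x 2 pops

    def test_method_validation(self, fixed_difference):
        with pytest.raises(ValueError):
            genic_test_global(fixed_difference, method="nope")

    def test_pairwise_layout(self, baseline):
        ds = generate_null_metapopulation(baseline, 4, 8, seed=21)
        mat = pairwise_differentiation(ds, method="chi2", seed=0)
        pops = ds.populations
        assert list(mat.index) == pops
        # theta below the diagonal, G'_ST above, diagonal empty
        assert not math.isnan(mat.iloc[2, 0])
        assert not math.isnan(mat.iloc[0, 2])
        assert math.isnan(mat.iloc[1, 1])
        assert mat.attrs["adjusted_alpha"] == pytest.approx(
            narum_adjust(0.05, 6))
        assert len(mat.attrs["p_values"]) == 6

    def test_chi2_genic_test_agrees_with_table_path(self, toy_two_pops):
        p1 = chi2_genic_test(toy_two_pops, "L1")
        table = genic_table(toy_two_pops, "L1")
        from msatpop.differentiation import chi2_genic_from_table
        assert p1 == chi2_genic_from_table(table)
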