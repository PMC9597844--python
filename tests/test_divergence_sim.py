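"""Drift-only and finite-island divergence simulators."""

import numpy as np
import pytest
from scipy import stats

from msatpop.differentiation import wc_theta
from msatpop.divergence_sim import (
    DriftScenario,
    IslandScenario,
    detect_differentiation,
    drift_populations,
    expected_fst,
    generations_for_expected_fst,
    island_model_sim,
    sample_genotypes,
)
from msatpop.genepop import AlleleFrequencyTable


def single_locus_pool(freqs: dict[int, float]) -> AlleleFrequencyTable:
    return AlleleFrequencyTable.single_pool(["L1"], {"L1": freqs})


class TestExpectedFst:
    @pytest.mark.parametrize("ne,t,val", [
        (1000, 0, 0.0),
        (1000, 20, 0.009952),
        (1000, 102, 0.049733),
    ])
    def test_closed_form(self, ne, t, val):
        assert expected_fst(ne, t) == pytest.approx(val, abs=1e-6)

    @pytest.mark.parametrize("level,t", [(0.001, 2), (0.0025, 5), (0.0, 0),
                                         (0.00995, 20), (0.0497, 102)])
    def test_level_to_generations(self, level, t):
        assert generations_for_expected_fst(level, 1000) == t

    def test_validation(self):
        with pytest.raises(ValueError):
            expected_fst(0, 5)
        with pytest.raises(ValueError):
            DriftScenario(t=-1)


class TestDriftPopulations:
    def test_t_zero_identity(self, baseline):
        table = drift_populations(baseline, 3, 1000, 0, seed=1)
        pool = baseline.populations[0]
        for pop in table.populations:
            for locus in baseline.loci:
                assert table.freqs[pop][locus] == baseline.freqs[pool][locus]

    def test_eventual_fixation(self):
        pool = single_locus_pool({1: 0.5, 2: 0.5})
        table = drift_populations(pool, 5, 10, 400, seed=2)
        for pop in table.populations:
            assert len(table.freqs[pop]["L1"]) == 1

    def test_martingale_mean_frequency(self):
        """Drift leaves the expected allele frequency unchanged."""
        pool = single_locus_pool({1: 0.3, 2: 0.7})
        table = drift_populations(pool, 2000, 50, 10, seed=3)
        freqs = np.array([table.freqs[p]["L1"].get(1, 0.0)
                          for p in table.populations])
        se = freqs.std(ddof=1) / np.sqrt(len(freqs))
        assert abs(freqs.mean() - 0.3) < 3 * se

    def test_realized_theta_tracks_expectation(self, baseline):
        vals = []
        for r in range(120):
            rng = np.random.default_rng((41, r))
            table = drift_populations(baseline, 14, 1000, 50, rng)
            ds = sample_genotypes(table, 50, rng)
            vals.append(wc_theta(ds).theta)
        exp = expected_fst(1000, 50)
        assert abs(np.mean(vals) - exp) / exp < 0.10


class TestSampleGenotypes:
    def test_monomorphic(self):
        ds = sample_genotypes(single_locus_pool({5: 1.0}), 12, seed=1)
        assert np.all(ds.genotypes[ds.populations[0]] == 5)

    def test_multinomial_gof(self):
        pool = single_locus_pool({1: 0.5, 2: 0.3, 3: 0.2})
        ds = sample_genotypes(pool, 5000, seed=2)
        counts = ds.allele_counts("L1", ds.populations[0])
        chi2, p = stats.chisquare(
            [counts[1], counts[2], counts[3]],
            f_exp=[0.5 * 10_000, 0.3 * 10_000, 0.2 * 10_000],
        )
        assert p > 0.001

    def test_unequal_sizes_mapping(self, baseline):
        table = drift_populations(baseline, 3, 1000, 0, seed=3)
        sizes = {p: s for p, s in zip(table.populations, (8, 12, 16))}
        ds = sample_genotypes(table, sizes, seed=4)
        assert [ds.n_individuals(p) for p in ds.populations] == [8, 12, 16]


class TestIslandModel:
    pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")

    def test_isolated_fixed_demes_theta_one(self):
        sc = IslandScenario(n_demes=2, ne=20, m=0.0, mu=0.0, s=10,
                            burn_in=200, n_loci=2, init_states=2)
        ds = island_model_sim(sc, seed=5)
        # with m = mu = 0 each deme fixes independently; keep loci where
        # the two demes fixed different alleles and expect theta = 1
        thetas = [v for v in wc_theta(ds).theta_per_locus.values()
                  if not np.isnan(v)]
        if thetas:
            assert np.allclose(thetas, 1.0)

    def test_strong_mixing_panmixia(self):
        vals = []
        for r in range(15):
            sc = IslandScenario(n_demes=2, ne=100, m=0.5, mu=0.0, s=30,
                                burn_in=50)
            vals.append(wc_theta(island_model_sim(sc, seed=(6, r))).theta)
        assert abs(np.mean(vals)) < 0.02

    def test_no_migration_no_mutation_allele_subset(self):
        sc = IslandScenario(n_demes=3, ne=30, m=0.0, mu=0.0, s=20,
                            burn_in=50, n_loci=3)
        ds = island_model_sim(sc, seed=7)
        start = set(range((5 + 60) // 2 - 5, (5 + 60) // 2 + 5))
        for pop in ds.populations:
            for locus in ds.loci:
                assert set(ds.allele_counts(locus, pop)) <= start

    def test_smm_equilibrium_heterozygosity(self):
        """Single isolated deme at mutation-drift equilibrium (SMM).

        Expectation 1 - 1/sqrt(1 + 8 Ne mu) at Ne=500, mu=5e-4.
        """
        sc = IslandScenario(n_demes=2, ne=500, m=0.0, mu=5e-4, s=50,
                            burn_in=5000, n_loci=8, init_states=1)
        vals = []
        for r in range(2):
            ds = island_model_sim(sc, seed=(8, r))
            for pop in ds.populations:
                for locus in ds.loci:
                    counts = ds.allele_counts(locus, pop)
                    tot = sum(counts.values())
                    p = np.array(list(counts.values())) / tot
                    vals.append(1 - np.sum(p * p))
        expected = 1 - 1 / np.sqrt(1 + 8 * 500 * 5e-4)
        assert abs(np.mean(vals) - expected) / expected < 0.20

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            IslandScenario(m=1.5)
        with pytest.raises(ValueError):
            IslandScenario(mu=-1e-4)


class TestDetection:
    def test_fixed_difference_always_detected(self, fixed_difference):
        assert detect_differentiation(fixed_difference, method="chi2")
        assert detect_differentiation(fixed_difference, method="fisher_mc",
                                      mc_reps=1000, seed=1)

    def test_single_population_errors(self):
        from conftest import dataset_from_calls
        ds = dataset_from_calls({"a": [[(1, 2)], [(1, 1)]]})
        with pytest.raises(ValueError):
            detect_differentiation(ds)

    def test_chi2_and_exact_concord_at_strong_divergence(self, baseline):
        """Both test variants agree when divergence is far above alpha."""
        agree = 0
        n = 60
        for r in range(n):
            rng = np.random.default_rng((51, r))
            table = drift_populations(baseline, 14, 1000, 102, rng)
            ds = sample_genotypes(table, 50, rng)
            a = detect_differentiation(ds, method="chi2")
            b = detect_differentiation(ds, method="fisher_mc", mc_reps=500,
                                       seed=rng)
            agree += a == b
        assert agree / n >= 0.9
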