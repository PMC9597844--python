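"""Between-population differentiation statistics and significance tests.

Estimators
----------
* Weir & Cockerham's theta, the moment estimator of F_ST built from the
  among-population (a), among-individual-within-population (b) and
  within-individual (c) variance components.  The multilocus value is the
  ratio of summed components, not a mean of per-locus ratios, and may be
  negative in undifferentiated samples.
* Nei's G_ST = (H_T - H_S)/H_T and Hedrick's standardized
  G'_ST = G_ST (k - 1 + H_S) / ((k - 1)(1 - H_S)), which rescales G_ST by
  its maximum attainable value given the within-population diversity so
  that highly polymorphic markers can reach 1.  Dataset-level values use
  the Nei–Chesser small-sample corrections of H_S and H_T; the raw
  frequency-parameter versions are exposed for hand-checked examples.

Tests
-----
Genic (allele-count) homogeneity tests per locus — either an asymptotic
chi-square on the allele × population contingency table or a Monte-Carlo
exact test that permutes gene copies among populations with fixed
margins.  Multi-locus combination follows the two classical conventions:
the chi-square statistic and its degrees of freedom are summed over
loci, whereas exact-test p-values are combined with Fisher's method with
single-locus p-values floored at 1e-4 so one locus cannot dominate the
global result.
Multiple testing across population pairs uses the Narum adjustment
``alpha / H_k`` (harmonic number), intermediate between Bonferroni and no
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genepop import GenotypeDataset

__all__ = [
    "DifferentiationResult",
    "DifferentiationTestResult",
    "wc_theta",
    "gst_from_frequencies",
    "hedrick_gprime_st",
    "differentiation",
    "bootstrap_ci",
    "chi2_genic_test",
    "exact_genic_test",
    "genic_test_global",
    "fisher_combine",
    "narum_adjust",
    "pairwise_differentiation",
]


@dataclass
class DifferentiationResult:
    """Point estimates of differentiation for one set of populations."""

    populations: list[str]
    theta: float = math.nan
    theta_per_locus: dict[str, float] = field(default_factory=dict)
    gst: float = math.nan
    gprime_st: float = math.nan
    hs: float = math.nan
    ht: float = math.nan
    k: int = 0
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class DifferentiationTestResult:
    """Fisher-combined genic test across loci."""

    p_per_locus: dict[str, float]
    chi2: float
    df: int
    p_global: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_global < alpha


# ----------------------------------------------------------------------
# Weir & Cockerham variance components
# ----------------------------------------------------------------------

def _wc_components_locus(ds: GenotypeDataset, locus: str, pops: Sequence[str]):
    """Summed (a, b, c) components over alleles at one locus."""
    n_i, p_mat, h_mat, alleles = [], [], [], None
    calls_by_pop = []
    for pop in pops:
        calls = ds.locus_calls(locus, pop)
        if len(calls) > 0:
            calls_by_pop.append(calls)
    if len(calls_by_pop) < 2:
        return 0.0, 0.0, 0.0
    allele_list = sorted(set(int(a) for c in calls_by_pop for a in c.ravel()))
    if len(allele_list) < 2:
        return 0.0, 0.0, 0.0
    index = {a: j for j, a in enumerate(allele_list)}
    k = len(allele_list)
    r = len(calls_by_pop)
    n = np.array([len(c) for c in calls_by_pop], dtype=float)
    p = np.zeros((r, k))
    h = np.zeros((r, k))
    for i, calls in enumerate(calls_by_pop):
        for a1, a2 in calls:
            p[i, index[int(a1)]] += 1
            p[i, index[int(a2)]] += 1
            if a1 != a2:
                h[i, index[int(a1)]] += 1
                h[i, index[int(a2)]] += 1
    p /= (2 * n)[:, None]
    h /= n[:, None]

    n_tot = n.sum()
    nbar = n_tot / r
    nc = (n_tot - np.sum(n * n) / n_tot) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / n_tot
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / n_tot

    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_theta(
    ds: GenotypeDataset, populations: Sequence[str] | None = None
) -> DifferentiationResult:
    """Weir–Cockerham theta, per locus and multilocus.

    The multilocus estimate is ``sum(a) / sum(a + b + c)`` over loci;
    loci monomorphic across all populations contribute nothing.
    """
    pops = list(populations or ds.populations)
    if len(pops) < 2:
        raise ValueError("theta needs at least two populations")
    per_locus: dict[str, float] = {}
    num = den = 0.0
    for locus in ds.loci:
        a, b, c = _wc_components_locus(ds, locus, pops)
        tot = a + b + c
        per_locus[locus] = a / tot if tot != 0 else math.nan
        num += a
        den += tot
    res = DifferentiationResult(populations=pops, k=len(pops))
    res.theta = num / den if den != 0 else math.nan
    res.theta_per_locus = per_locus
    return res


# ----------------------------------------------------------------------
# G-statistics
# ----------------------------------------------------------------------

def gst_from_frequencies(p_mat: np.ndarray) -> DifferentiationResult:
    """Raw (frequency-parameter) G_ST and G'_ST from a pops × alleles matrix.

    Populations are weighted equally; no sample-size correction.  This is
    the textbook definition used for hand-checked examples and for
    diagnostics on simulators that know their true frequencies.
    """
    p = np.asarray(p_mat, dtype=float)
    k = p.shape[0]
    if k < 2:
        raise ValueError("need at least two populations")
    hs = float(np.mean(1.0 - np.sum(p * p, axis=1)))
    pbar = p.mean(axis=0)
    ht = float(1.0 - np.sum(pbar * pbar))
    res = DifferentiationResult(populations=[f"pop_{i}" for i in range(k)], k=k,
                                hs=hs, ht=ht)
    if ht <= 0:
        return res  # undefined: every population fixed for the same allele
    res.gst = (ht - hs) / ht
    if hs < 1:
        res.gprime_st = res.gst * (k - 1 + hs) / ((k - 1) * (1 - hs))
    return res


def hedrick_gprime_st(p_mats: Sequence[np.ndarray] | np.ndarray) -> DifferentiationResult:
    """Multilocus raw G'_ST from per-locus pops × alleles frequency matrices.

    H_S and H_T are averaged over loci before forming the ratios.
    """
    if isinstance(p_mats, np.ndarray) and p_mats.ndim == 2:
        p_mats = [p_mats]
    hs_vals, ht_vals, k = [], [], None
    for mat in p_mats:
        r = gst_from_frequencies(mat)
        k = r.k
        hs_vals.append(r.hs)
        ht_vals.append(r.ht)
    hs, ht = float(np.mean(hs_vals)), float(np.mean(ht_vals))
    res = DifferentiationResult(populations=[], k=k or 0, hs=hs, ht=ht)
    if ht > 0:
        res.gst = (ht - hs) / ht
        if hs < 1:
            res.gprime_st = res.gst * (k - 1 + hs) / ((k - 1) * (1 - hs))
    return res


def _nei_chesser_locus(ds: GenotypeDataset, locus: str, pops: Sequence[str]):
    """Bias-corrected (H_S, H_T) at one locus; None if undefined."""
    ns, freqs, hos = [], [], []
    for pop in pops:
        calls = ds.locus_calls(locus, pop)
        if len(calls) == 0:
            continue
        counts = {}
        for a1, a2 in calls:
            counts[int(a1)] = counts.get(int(a1), 0) + 1
            counts[int(a2)] = counts.get(int(a2), 0) + 1
        tot = 2 * len(calls)
        ns.append(len(calls))
        freqs.append({a: c / tot for a, c in counts.items()})
        hos.append(float(np.mean(calls[:, 0] != calls[:, 1])))
    r = len(ns)
    if r < 2:
        return None
    alleles = sorted({a for f in freqs for a in f})
    p = np.array([[f.get(a, 0.0) for a in alleles] for f in freqs])
    n_harm = r / np.sum(1.0 / np.asarray(ns, dtype=float))
    ho = float(np.mean(hos))
    hs_raw = float(np.mean(1.0 - np.sum(p * p, axis=1)))
    pbar = p.mean(axis=0)
    ht_raw = float(1.0 - np.sum(pbar * pbar))
    hs = n_harm / (n_harm - 1) * (hs_raw - ho / (2 * n_harm))
    ht = ht_raw + hs / (n_harm * r) - ho / (2 * n_harm * r)
    return hs, ht


def differentiation(
    ds: GenotypeDataset, populations: Sequence[str] | None = None
) -> DifferentiationResult:
    """Dataset-level multilocus theta, G_ST and Hedrick's G'_ST.

    G-statistics use the Nei–Chesser small-sample corrections of H_S and
    H_T (harmonic-mean sample size, observed-heterozygosity terms),
    averaged over loci before forming the ratios.
    """
    pops = list(populations or ds.populations)
    res = wc_theta(ds, pops)
    hs_vals, ht_vals = [], []
    for locus in ds.loci:
        pair = _nei_chesser_locus(ds, locus, pops)
        if pair is not None:
            hs_vals.append(pair[0])
            ht_vals.append(pair[1])
    if hs_vals:
        hs, ht = float(np.mean(hs_vals)), float(np.mean(ht_vals))
        res.hs, res.ht = hs, ht
        if ht > 0:
            res.gst = (ht - hs) / ht
            if hs < 1:
                k = len(pops)
                res.gprime_st = res.gst * (k - 1 + hs) / ((k - 1) * (1 - hs))
    return res


def bootstrap_ci(
    ds: GenotypeDataset,
    statistic: str = "theta",
    reps: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    populations: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Bootstrap CI, resampling individuals within populations.

    ``statistic`` is ``"theta"`` or ``"gprime_st"``.  The percentile
    interval is recentred on the point estimate: duplicated individuals
    make the resampled estimator biased upward by O(1/S), and without
    the shift null datasets would produce intervals that exclude zero.
    Deterministic under a fixed seed.
    """
    if statistic not in ("theta", "gprime_st", "gst"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if reps < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    pops = list(populations or ds.populations)
    for pop in pops:
        if ds.n_individuals(pop) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for b in range(reps):
        resampled = {}
        for pop in pops:
            arr = ds.genotypes[pop]
            idx = rng.integers(0, len(arr), size=len(arr))
            resampled[pop] = arr[idx]
        boot = GenotypeDataset(loci=ds.loci, genotypes=resampled)
        res = differentiation(boot) if statistic != "theta" else wc_theta(boot)
        vals[b] = getattr(res, statistic)
    vals = vals[~np.isnan(vals)]
    point_res = differentiation(ds, pops) if statistic != "theta" else \
        wc_theta(ds, pops)
    point = getattr(point_res, statistic)
    shift = point - float(vals.mean())  # remove the resampling bias
    lo, hi = np.percentile(vals, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo + shift), float(hi + shift)


# ----------------------------------------------------------------------
# Genic homogeneity tests
# ----------------------------------------------------------------------

def genic_table(
    ds: GenotypeDataset, locus: str, populations: Sequence[str] | None = None
) -> np.ndarray:
    """Allele × population gene-copy contingency table (non-empty rows/cols)."""
    pops = list(populations or ds.populations)
    alleles = sorted(ds.observed_alleles(locus))
    idx = {a: i for i, a in enumerate(alleles)}
    table = np.zeros((len(alleles), len(pops)), dtype=np.int64)
    for j, pop in enumerate(pops):
        for a, c in ds.allele_counts(locus, pop).items():
            table[idx[a], j] = c
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return table


def chi2_genic_from_table(table: np.ndarray) -> float:
    """Asymptotic chi-square p-value for homogeneity of allele counts."""
    table = np.asarray(table, dtype=float)
    if table.size == 0 or table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = (table - expected) ** 2 / expected
    stat = float(np.nansum(cells))
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(stats.chi2.sf(stat, df))


def mc_exact_from_table(
    table: np.ndarray, reps: int = 10_000, seed: int | np.random.Generator = 0
) -> float:
    """Monte-Carlo exact p-value with fixed margins.

    Simulated tables are produced by randomly permuting the pooled gene
    copies among populations; the orderings statistic is the conditional
    table probability, and ``p = (1 + #{P_sim <= P_obs}) / (reps + 1)``
    so the p-value can never be exactly zero.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.size == 0:
        raise ValueError("empty contingency table")
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    n_alleles, n_pops = table.shape
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    pool = np.repeat(np.arange(n_alleles), row)
    pos_pop = np.repeat(np.arange(n_pops), col)
    n = pool.size

    # varying part of log P(table | margins): -sum log T_ij!
    def log_stat(t):
        return -float(gammaln(t + 1).sum())

    obs = log_stat(table)
    perms = rng.permuted(np.tile(pool, (reps, 1)), axis=1)
    flat = (
        np.repeat(np.arange(reps), n) * (n_alleles * n_pops)
        + perms.ravel() * n_pops
        + np.tile(pos_pop, reps)
    )
    sim_tables = np.bincount(flat, minlength=reps * n_alleles * n_pops).reshape(
        reps, n_alleles, n_pops
    )
    sim = -gammaln(sim_tables + 1).sum(axis=(1, 2))
    hits = int(np.sum(sim <= obs + 1e-9))
    return (1 + hits) / (reps + 1)


def chi2_genic_test(
    ds: GenotypeDataset, locus: str, populations: Sequence[str] | None = None
) -> float:
    return chi2_genic_from_table(genic_table(ds, locus, populations))


def exact_genic_test(
    ds: GenotypeDataset,
    locus: str,
    populations: Sequence[str] | None = None,
    mc_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> float:
    return mc_exact_from_table(genic_table(ds, locus, populations), mc_reps, seed)


def fisher_combine(
    p_values: Sequence[float], floor: float = 1e-4
) -> tuple[float, int, float]:
    """Fisher's combination of per-locus p-values with a lower floor.

    Each p is clipped from below at ``floor`` before combining, so no
    single locus can dominate; returns ``(chi2, df, global_p)`` with
    ``df = 2L``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    p = np.maximum(p, floor)
    chi2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def narum_adjust(alpha: float = 0.05, k: int = 1) -> float:
    """Narum's multiple-testing adjustment ``alpha / sum_{i=1..k} 1/i``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / float(np.sum(1.0 / np.arange(1, k + 1)))


def genic_test_global(
    ds: GenotypeDataset,
    populations: Sequence[str] | None = None,
    method: str = "chi2",
    mc_reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    floor: float = 1e-4,
) -> DifferentiationTestResult:
    """Multi-locus genic homogeneity test.

    ``method="chi2"`` sums the Pearson chi-square statistic and its
    degrees of freedom over loci (the convention of classical
    power-simulation tools, where every locus contributes its raw
    statistic); ``method="fisher_mc"`` runs the per-locus Monte-Carlo
    exact test and combines p-values with Fisher's method and the
    single-locus floor; ``method="chi2_fisher"`` Fisher-combines the
    per-locus asymptotic chi-square p-values instead.
    """
    if method not in ("chi2", "fisher_mc", "chi2_fisher"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    p_per_locus: dict[str, float] = {}
    if method == "chi2":
        stat_tot, df_tot = 0.0, 0
        for locus in ds.loci:
            table = genic_table(ds, locus, populations).astype(float)
            if table.shape[0] < 2 or table.shape[1] < 2:
                p_per_locus[locus] = 1.0
                continue
            row, col = table.sum(axis=1), table.sum(axis=0)
            expected = np.outer(row, col) / table.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = float(np.nansum((table - expected) ** 2 / expected))
            df = (table.shape[0] - 1) * (table.shape[1] - 1)
            p_per_locus[locus] = float(stats.chi2.sf(stat, df))
            stat_tot += stat
            df_tot += df
        p = float(stats.chi2.sf(stat_tot, df_tot)) if df_tot else 1.0
        return DifferentiationTestResult(p_per_locus=p_per_locus, chi2=stat_tot,
                                         df=df_tot, p_global=p)
    for locus in ds.loci:
        table = genic_table(ds, locus, populations)
        if method == "chi2_fisher":
            p_per_locus[locus] = chi2_genic_from_table(table)
        else:
            p_per_locus[locus] = mc_exact_from_table(table, mc_reps, rng)
    chi2, df, p = fisher_combine(p_per_locus.values(), floor=floor)
    return DifferentiationTestResult(p_per_locus=p_per_locus, chi2=chi2, df=df,
                                     p_global=p)


def pairwise_differentiation(
    ds: GenotypeDataset,
    method: str = "fisher_mc",
    mc_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pairwise differentiation matrix in the conventional layout.

    Theta below the diagonal, Hedrick's G'_ST above; the companion
    ``attrs`` carry the pairwise global p-values and the Narum-adjusted
    alpha over the C(k, 2) pairs.
    """
    pops = ds.populations
    k = len(pops)
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(np.nan, index=pops, columns=pops)
    pvals: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            pair = [pops[i], pops[j]]
            res = differentiation(ds, pair)
            mat.iloc[j, i] = res.theta
            mat.iloc[i, j] = res.gprime_st
            test = genic_test_global(ds, pair, method=method, mc_reps=mc_reps,
                                     seed=rng)
            pvals[(pops[i], pops[j])] = test.p_global
    adj = narum_adjust(alpha, k * (k - 1) // 2)
    mat.attrs["p_values"] = pvals
    mat.attrs["adjusted_alpha"] = adj
    mat.attrs["significant_pairs"] = sorted(
        pair for pair, p in pvals.items() if p < adj
    )
    return mat
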