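"""Within-population diversity metrics for microsatellite data.

Implements the usual single-population summary set: number of alleles
(``N_A``), rarefied allelic richness (``A_R``), effective number of
alleles (``A_E``), expected/observed heterozygosity (``H_E``/``H_O``),
Nei's unbiased expected heterozygosity (``uH_E``) and the inbreeding
coefficient ``F_IS = 1 - H_O/H_E``.  Rarefaction uses the exact
hypergeometric expectation

    A_R(g) = sum_i [ 1 - C(N - N_i, g) / C(N, g) ]

evaluated in log space so that gene-copy totals in the thousands do not
overflow.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genepop import GenotypeDataset

__all__ = [
    "expected_heterozygosity",
    "unbiased_expected_heterozygosity",
    "observed_heterozygosity",
    "effective_alleles",
    "allelic_richness",
    "inbreeding_coefficient",
    "summarize_population",
    "summarize",
]

METRICS = ["n_alleles", "allelic_richness", "effective_alleles",
           "exp_het", "obs_het", "unbiased_exp_het", "f_is"]


def _freq_array(freqs: Mapping[int, float] | Sequence[float]) -> np.ndarray:
    if isinstance(freqs, Mapping):
        p = np.asarray(list(freqs.values()), dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency map")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p


def expected_heterozygosity(freqs: Mapping[int, float] | Sequence[float]) -> float:
    """Gene diversity ``H_E = 1 - sum(p_i^2)``."""
    p = _freq_array(freqs)
    return float(1.0 - np.sum(p * p))


def unbiased_expected_heterozygosity(
    freqs: Mapping[int, float] | Sequence[float], n_individuals: int
) -> float:
    """Nei's small-sample corrected gene diversity ``2N/(2N-1) * H_E``."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    two_n = 2 * n_individuals
    return two_n / (two_n - 1) * expected_heterozygosity(freqs)


def observed_heterozygosity(calls: np.ndarray) -> float:
    """Fraction of non-missing diploid calls whose two alleles differ.

    ``calls`` is an ``(m, 2)`` array of non-missing calls (see
    :meth:`GenotypeDataset.locus_calls`).
    """
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("no non-missing calls")
    return float(np.mean(calls[:, 0] != calls[:, 1]))


def effective_alleles(freqs: Mapping[int, float] | Sequence[float]) -> float:
    """Effective number of alleles ``A_E = 1 / sum(p_i^2)``."""
    p = _freq_array(freqs)
    return float(1.0 / np.sum(p * p))


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(n >= k, out, -np.inf)


def allelic_richness(counts: Mapping[int, int] | Sequence[int], g: int) -> float:
    """Expected number of alleles in a random subsample of ``g`` gene copies.

    Exact hypergeometric rarefaction; ``C(a, b)`` is taken as 0 when
    ``a < b`` so alleles with fewer than ``N - g`` copies always survive.
    """
    if isinstance(counts, Mapping):
        c = np.asarray(list(counts.values()), dtype=float)
    else:
        c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty allele count map")
    n_tot = c.sum()
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    if g > n_tot:
        raise ValueError(f"rarefaction size g={g} exceeds {int(n_tot)} gene copies")
    log_denom = _log_comb(n_tot, g)
    log_num = _log_comb(n_tot - c, g)
    return float(np.sum(1.0 - np.exp(log_num - log_denom)))


def inbreeding_coefficient(exp_het: float, obs_het: float) -> float:
    """``F_IS = 1 - H_O / H_E``; NaN when the locus is monomorphic."""
    if exp_het <= 0:
        return math.nan
    return 1.0 - obs_het / exp_het


# ----------------------------------------------------------------------

def _locus_row(ds: GenotypeDataset, population: str, locus: str, g: int | None):
    counts = ds.allele_counts(locus, population)
    n_copies = sum(counts.values())
    if n_copies == 0:
        return {m: math.nan for m in METRICS}
    freqs = {a: c / n_copies for a, c in counts.items()}
    he = expected_heterozygosity(freqs)
    ho = observed_heterozygosity(ds.locus_calls(locus, population))
    return {
        "n_alleles": float(len(counts)),
        "allelic_richness": allelic_richness(counts, g) if g else math.nan,
        "effective_alleles": effective_alleles(freqs),
        "exp_het": he,
        "obs_het": ho,
        "unbiased_exp_het": n_copies / (n_copies - 1) * he if n_copies > 1 else he,
        "f_is": inbreeding_coefficient(he, ho),
    }


def min_gene_copies(ds: GenotypeDataset, populations: Sequence[str] | None = None) -> int:
    """Smallest per-locus gene-copy count over populations (rarefaction base)."""
    pops = populations or ds.populations
    vals = [
        sum(ds.allele_counts(locus, pop).values())
        for pop in pops
        for locus in ds.loci
    ]
    return int(min(vals))


def summarize_population(
    ds: GenotypeDataset, population: str, g: int | None = None
) -> pd.DataFrame:
    """Per-locus diversity metrics for one population.

    ``g`` is the rarefaction size in gene copies; ``None`` skips the
    allelic-richness column (it needs a cross-population standard).
    """
    rows = {locus: _locus_row(ds, population, locus, g) for locus in ds.loci}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "locus"
    return df


def summarize(
    ds: GenotypeDataset, g: int | None = None, populations: Sequence[str] | None = None
) -> pd.DataFrame:
    """Table-style summary: per population, mean ± SE over loci.

    Returns a DataFrame indexed by population with ``<metric>`` and
    ``<metric>_se`` columns for each of the seven metrics.  The SE is the
    sample standard deviation over loci divided by sqrt(L); F_IS at
    monomorphic loci is undefined and excluded from its mean.
    """
    pops = list(populations or ds.populations)
    if g is None:
        g = min_gene_copies(ds, pops)
    out = {}
    for pop in pops:
        per_locus = summarize_population(ds, pop, g)
        row = {}
        for m in METRICS:
            vals = per_locus[m].dropna().to_numpy()
            row[m] = float(np.mean(vals)) if vals.size else math.nan
            row[f"{m}_se"] = (
                float(np.std(vals, ddof=1) / math.sqrt(vals.size))
                if vals.size > 1 else 0.0
            )
        out[pop] = row
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "population"
    df.attrs["rarefaction_g"] = g
    return df
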