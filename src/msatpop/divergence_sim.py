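"""Divergence simulators for power analysis of differentiation tests.

Two generative models are provided:

* a drift-only model in which every population starts from the same
  baseline allele frequencies and drifts independently for ``t``
  Wright-Fisher generations at effective size ``Ne`` (no migration,
  mutation or selection), so the expected divergence is
  ``F_ST = 1 - (1 - 1/(2 Ne))^t``;
* a symmetric finite island model: ``n`` demes of size ``Ne`` exchange
  gametes at rate ``m`` (an immigrant copy comes from a uniformly chosen
  other deme) with stepwise mutation at rate ``mu`` per gene copy per
  generation (+/-1 repeat unit, reflecting at the repeat-count bounds).
  Absent mutation the classical equilibrium expectation is
  ``F_ST ~ 1 / (1 + 4 Ne m (n/(n-1))^2)``.

Both emit :class:`~msatpop.genepop.GenotypeDataset` samples so the same
test machinery runs on simulated and empirical data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .differentiation import genic_test_global, gst_from_frequencies
from .genepop import AlleleFrequencyTable, GenotypeDataset

__all__ = [
    "DriftScenario",
    "IslandScenario",
    "expected_fst",
    "generations_for_expected_fst",
    "drift_populations",
    "sample_genotypes",
    "island_model_sim",
    "detect_differentiation",
]


@dataclass(frozen=True)
class DriftScenario:
    """Drift-only divergence design: N populations, Ne, t generations."""

    n_pops: int = 14
    ne: int = 1000
    t: int = 0
    s: int = 10
    replicates: int = 1000

    def __post_init__(self) -> None:
        if self.t < 0 or self.ne < 1 or self.n_pops < 2 or self.s < 1:
            raise ValueError("invalid drift scenario")


@dataclass(frozen=True)
class IslandScenario:
    """Symmetric finite island model design."""

    n_demes: int = 10
    ne: int = 100
    m: float = 0.01
    n_loci: int = 8
    mu: float = 5e-4
    s: int = 50
    burn_in: int | None = None  # default 10 * Ne generations
    repeat_bounds: tuple[int, int] = (5, 60)
    init_states: int = 10  # distinct starting repeat counts per locus

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("migration rate must be in [0, 1]")
        if self.mu < 0:
            raise ValueError("mutation rate must be >= 0")
        if self.n_demes < 2 or self.ne < 2 or self.s < 1:
            raise ValueError("invalid island scenario")

    @property
    def burn_in_generations(self) -> int:
        return self.burn_in if self.burn_in is not None else 10 * self.ne


def expected_fst(ne: int, t: int) -> float:
    """Drift expectation ``1 - (1 - 1/(2 Ne))^t``."""
    if ne < 1 or t < 0:
        raise ValueError("need Ne >= 1 and t >= 0")
    return 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** t


def generations_for_expected_fst(fst: float, ne: int) -> int:
    """Smallest integer t whose drift expectation is closest to ``fst``."""
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if fst == 0.0:
        return 0
    t_exact = math.log1p(-fst) / math.log1p(-1.0 / (2.0 * ne))
    return max(0, round(t_exact))


def _locus_arrays(cell: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray]:
    alleles = np.array(sorted(cell), dtype=np.int64)
    probs = np.array([cell[a] for a in alleles], dtype=float)
    return alleles, probs / probs.sum()


def drift_populations(
    baseline: AlleleFrequencyTable,
    n_pops: int,
    ne: int,
    t: int,
    seed: int | np.random.Generator = 0,
    pool: str | None = None,
) -> AlleleFrequencyTable:
    """Drift ``n_pops`` independent populations from a common baseline.

    Each generation resamples 2*Ne gene copies per locus (multinomial);
    ``t = 0`` returns the baseline frequencies for all populations.
    """
    rng = np.random.default_rng(seed)
    pool = pool or baseline.populations[0]
    labels = [f"pop_{i + 1}" for i in range(n_pops)]
    freqs: dict[str, dict[str, dict[int, float]]] = {lab: {} for lab in labels}
    n: dict[str, dict[str, int]] = {lab: {} for lab in labels}
    copies = 2 * ne
    for locus in baseline.loci:
        if t == 0:  # bit-identical to the baseline by contract
            for lab in labels:
                freqs[lab][locus] = dict(baseline.freqs[pool][locus])
                n[lab][locus] = copies
            continue
        alleles, p0 = _locus_arrays(baseline.freqs[pool][locus])
        p = np.tile(p0, (n_pops, 1))
        for _ in range(t):
            counts = rng.multinomial(copies, p)
            p = counts / copies
        for i, lab in enumerate(labels):
            nz = p[i] > 0
            freqs[lab][locus] = {
                int(a): float(f) for a, f in zip(alleles[nz], p[i][nz])
            }
            n[lab][locus] = copies
    return AlleleFrequencyTable(loci=list(baseline.loci), freqs=freqs, n=n)


def sample_genotypes(
    table: AlleleFrequencyTable,
    s: int | Mapping[str, int],
    seed: int | np.random.Generator = 0,
) -> GenotypeDataset:
    """Sample diploid genotypes from a frequency table under HWE.

    ``s`` is the number of individuals per population (a mapping allows
    unequal sizes).  2s gene copies per locus are drawn multinomially and
    paired at random into s individuals.
    """
    rng = np.random.default_rng(seed)
    genotypes: dict[str, np.ndarray] = {}
    for pop in table.populations:
        n_ind = s[pop] if isinstance(s, Mapping) else int(s)
        if n_ind < 1:
            raise ValueError("sample size must be >= 1")
        arr = np.zeros((n_ind, len(table.loci), 2), dtype=np.int64)
        for l, locus in enumerate(table.loci):
            cell = table.freqs[pop][locus]
            if not cell:
                raise ValueError(f"empty frequency cell {pop}/{locus}")
            alleles, p = _locus_arrays(cell)
            counts = rng.multinomial(2 * n_ind, p)
            copies = np.repeat(alleles, counts)
            rng.shuffle(copies)
            arr[:, l, :] = copies.reshape(n_ind, 2)
        genotypes[pop] = arr
    return GenotypeDataset(loci=list(table.loci), genotypes=genotypes)


# ----------------------------------------------------------------------
# Finite island model
# ----------------------------------------------------------------------

def _island_generation(
    pools: np.ndarray, m: float, mu: float, bounds: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """One Wright-Fisher generation with gamete migration and SMM mutation.

    ``pools`` has shape (n_demes, 2*Ne) of repeat counts.
    """
    n_demes, copies = pools.shape
    src = np.tile(np.arange(n_demes)[:, None], (1, copies))
    if m > 0:
        migrant = rng.random(pools.shape) < m
        # a migrant copy comes from a uniformly chosen *other* deme
        shift = rng.integers(1, n_demes, size=pools.shape)
        src = np.where(migrant, (src + shift) % n_demes, src)
    idx = rng.integers(0, copies, size=pools.shape)
    new = pools[src, idx]
    if mu > 0:
        mut = rng.random(pools.shape) < mu
        if mut.any():
            step = rng.choice([-1, 1], size=int(mut.sum()))
            vals = new[mut] + step
            lo, hi = bounds
            vals = np.where(vals < lo, lo + 1, vals)  # reflect at the bounds
            vals = np.where(vals > hi, hi - 1, vals)
            new[mut] = vals
    return new


def _pool_fst(pools_by_locus: list[np.ndarray]) -> float:
    """Raw multilocus G_ST of the deme gene pools (diagnostic)."""
    mats = []
    for pools in pools_by_locus:
        alleles = np.unique(pools)
        mat = np.stack([
            (pools == a).mean(axis=1) for a in alleles
        ], axis=1)
        mats.append(mat)
    hs = np.mean([gst_from_frequencies(m).hs for m in mats])
    ht = np.mean([gst_from_frequencies(m).ht for m in mats])
    return float((ht - hs) / ht) if ht > 0 else math.nan


def island_model_sim(
    scenario: IslandScenario,
    seed: int | np.random.Generator = 0,
    monitor_every: int | None = None,
) -> GenotypeDataset:
    """Simulate the finite island model and sample S diploids per deme.

    All demes start from an identical, maximally mixed gene pool (the
    ``init_states`` central repeat counts in equal proportion), run for
    the burn-in period, and are then sampled under HWE.  If the realized
    F_ST still trends by more than 10% between the last two monitoring
    windows a non-convergence warning is recorded in
    ``dataset.attrs["convergence_warning"]``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = scenario.repeat_bounds
    n_states = min(scenario.init_states, hi - lo + 1)
    start = (lo + hi) // 2 - n_states // 2
    states = np.arange(start, start + n_states)
    copies = 2 * scenario.ne
    base = np.resize(states, copies)
    pools = [
        np.tile(base, (scenario.n_demes, 1)).copy()
        for _ in range(scenario.n_loci)
    ]
    burn = scenario.burn_in_generations
    window = monitor_every or max(1, burn // 4)
    history: list[float] = []
    for gen in range(1, burn + 1):
        for l in range(scenario.n_loci):
            pools[l] = _island_generation(pools[l], scenario.m, scenario.mu,
                                          scenario.repeat_bounds, rng)
        if gen % window == 0 or gen == burn:
            history.append(_pool_fst(pools))

    warning = None
    # relative trend is meaningless around F_ST ~ 0 (panmictic cells)
    if len(history) >= 2 and history[-2] > 0.01:
        drift_trend = abs(history[-1] - history[-2]) / abs(history[-2])
        if drift_trend > 0.10:
            warning = (
                f"F_ST still trending ({history[-2]:.4f} -> {history[-1]:.4f}) "
                f"after {burn} burn-in generations"
            )
            warnings.warn(warning, RuntimeWarning, stacklevel=2)

    loci = [f"L{l + 1}" for l in range(scenario.n_loci)]
    genotypes: dict[str, np.ndarray] = {}
    for d in range(scenario.n_demes):
        arr = np.zeros((scenario.s, scenario.n_loci, 2), dtype=np.int64)
        for l in range(scenario.n_loci):
            draws = rng.choice(pools[l][d], size=2 * scenario.s, replace=True)
            arr[:, l, :] = draws.reshape(scenario.s, 2)
        genotypes[f"deme_{d + 1}"] = arr
    ds = GenotypeDataset(loci=loci, genotypes=genotypes)
    ds.attrs = {"fst_history": history, "convergence_warning": warning}
    return ds


def detect_differentiation(
    ds: GenotypeDataset,
    alpha: float = 0.05,
    method: str = "chi2",
    mc_reps: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> bool:
    """Is the Fisher-combined multi-locus genic test significant?"""
    if len(ds.populations) < 2:
        raise ValueError("need at least two populations")
    res = genic_test_global(ds, method=method, mc_reps=mc_reps, seed=seed)
    return res.p_global < alpha
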