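"""Forward-time simulation of an isolated population with overlapping
generations and bottleneck scenarios.

The model is an age-structured, constant-size, monoecious population with
random mating and no selfing: every year each individual ages by one
year, individuals beyond the maximum lifespan die, and new age-0 recruits
are produced by pairs of distinct mature parents until the target census
size (equated with the effective size N_e) is restored.  A bottleneck is
a one-off drop of the target size at a given year; the excess survivors
are culled uniformly at random.  There is no mutation, migration or
selection, so the allele set can only shrink — the quantity of interest
is how fast allelic diversity and heterozygosity erode at different N_e.

Setting ``longevity = 0`` switches the life cycle to discrete
(non-overlapping) generations: the whole population is replaced each
step by offspring of the current individuals, i.e. a Wright–Fisher model
without selfing.  This mode exists to validate the simulator against the
closed-form heterozygosity decay ``H_t = H_0 (1 - 1/(2N))^t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genepop import MISSING, AlleleFrequencyTable, GenotypeDataset

__all__ = [
    "LifeCycleConfig",
    "BottleneckScenario",
    "PopulationState",
    "TrajectorySummary",
    "initialize_population",
    "advance_year",
    "run_scenario",
    "simulate_population",
]

METRICS = ("n_alleles", "effective_alleles", "exp_het", "obs_het")


@dataclass(frozen=True)
class LifeCycleConfig:
    """Life-cycle parameters of the overlapping-generation model.

    ``longevity`` is the maximum age in years (death strikes at
    ``age > longevity``); ``maturity_age`` the first reproductive age;
    ``generation_overlap`` the fraction of founders given a random
    starting age (1.0 = fully mixed age structure).  ``longevity = 0``
    selects the discrete-generation Wright–Fisher mode.
    """

    longevity: int = 20
    maturity_age: int = 2
    generation_overlap: float = 1.0

    def __post_init__(self) -> None:
        if self.longevity < 0:
            raise ValueError("longevity must be >= 0")
        if self.longevity and not 0 < self.maturity_age < self.longevity:
            raise ValueError("need 0 < maturity_age < longevity")
        if not 0.0 <= self.generation_overlap <= 1.0:
            raise ValueError("generation_overlap must be in [0, 1]")

    @property
    def wright_fisher(self) -> bool:
        return self.longevity == 0


@dataclass(frozen=True)
class BottleneckScenario:
    """A single-step census-size history N0 -> N_post at ``bottleneck_year``."""

    n0: int = 500
    n_post: int = 500
    bottleneck_year: int = 1
    years: int = 100

    def __post_init__(self) -> None:
        if self.n_post > self.n0:
            raise ValueError("post-bottleneck size cannot exceed the initial size")
        if self.years < 1:
            raise ValueError("duration must be >= 1 year")

    def target_size(self, year: int) -> int:
        return self.n_post if year >= self.bottleneck_year else self.n0


@dataclass
class PopulationState:
    """Ages and genotypes of the living individuals."""

    loci: list[str]
    genotypes: np.ndarray  # (N, L, 2) allele codes
    ages: np.ndarray  # (N,)

    @property
    def size(self) -> int:
        return len(self.ages)

    def metrics(self) -> dict[str, float]:
        """Mean-over-loci N_A, A_E, H_E, H_O of the current population."""
        g = self.genotypes
        na, ae, he, ho = [], [], [], []
        for l in range(g.shape[1]):
            copies = g[:, l, :].ravel()
            copies = copies[copies != MISSING]
            counts = np.bincount(copies)
            counts = counts[counts > 0]
            p = counts / counts.sum()
            sum_p2 = float(np.sum(p * p))
            na.append(len(counts))
            ae.append(1.0 / sum_p2)
            he.append(1.0 - sum_p2)
            ho.append(float(np.mean(g[:, l, 0] != g[:, l, 1])))
        return {
            "n_alleles": float(np.mean(na)),
            "effective_alleles": float(np.mean(ae)),
            "exp_het": float(np.mean(he)),
            "obs_het": float(np.mean(ho)),
        }

    def allele_set(self) -> set[int]:
        vals = np.unique(self.genotypes)
        return {int(v) for v in vals if v != MISSING}

    def to_dataset(self, label: str = "sim") -> GenotypeDataset:
        return GenotypeDataset(loci=self.loci,
                               genotypes={label: self.genotypes.copy()})


@dataclass
class TrajectorySummary:
    """Yearly metric trajectories averaged over replicates."""

    years: np.ndarray
    mean: pd.DataFrame  # years × metrics
    sd: pd.DataFrame
    replicates: int
    per_replicate: np.ndarray | None = None  # (reps, years+1, metrics)
    final_states: list[PopulationState] = field(default_factory=list)

    def retention(self, metric: str, year: int) -> float:
        """Mean metric at ``year`` relative to its year-0 mean."""
        start = self.mean.loc[0, metric]
        if start == 0:
            raise ZeroDivisionError(f"{metric} is zero at year 0")
        return float(self.mean.loc[year, metric] / start)


# ----------------------------------------------------------------------

def initialize_population(
    source: GenotypeDataset | AlleleFrequencyTable,
    n: int,
    cfg: LifeCycleConfig,
    rng: int | np.random.Generator = 0,
    population: str | None = None,
) -> PopulationState:
    """Found a population of ``n`` individuals from empirical material.

    A :class:`GenotypeDataset` source is resampled individual-by-
    individual with replacement (preserving within-individual allele
    associations); an :class:`AlleleFrequencyTable` source yields
    Hardy–Weinberg draws.  Ages follow the configured overlap degree.
    """
    if n < 2:
        raise ValueError("cannot found a population with fewer than 2 individuals")
    rng = np.random.default_rng(rng)
    if isinstance(source, GenotypeDataset):
        pop = population or source.populations[0]
        arr = source.genotypes[pop]
        if len(arr) == 0:
            raise ValueError(f"source population {pop!r} is empty")
        idx = rng.integers(0, len(arr), size=n)
        genotypes = arr[idx].copy()
        loci = list(source.loci)
    else:
        pop = population or source.populations[0]
        loci = list(source.loci)
        genotypes = np.zeros((n, len(loci), 2), dtype=np.int64)
        for l, locus in enumerate(loci):
            cell = source.freqs[pop][locus]
            if not cell:
                raise ValueError(f"empty frequency cell at locus {locus!r}")
            alleles = np.array(list(cell.keys()))
            probs = np.array(list(cell.values()))
            draws = rng.choice(alleles, size=(n, 2), p=probs / probs.sum())
            genotypes[:, l, :] = draws
    if cfg.wright_fisher:
        ages = np.zeros(n, dtype=np.int64)
    else:
        ages = rng.integers(0, cfg.longevity, size=n)
        n_young = n - int(round(cfg.generation_overlap * n))
        if n_young > 0:
            ages[rng.choice(n, size=n_young, replace=False)] = 0
    return PopulationState(loci=loci, genotypes=genotypes, ages=ages)


def _recruit(
    parents_geno: np.ndarray, n_recruits: int, rng: np.random.Generator
) -> np.ndarray:
    """Offspring genotypes from random distinct-parent pairs (no selfing)."""
    m, n_loci, _ = parents_geno.shape
    p1 = rng.integers(0, m, size=n_recruits)
    p2 = rng.integers(0, m - 1, size=n_recruits)
    p2 = np.where(p2 >= p1, p2 + 1, p2)  # shift to exclude selfing
    pick1 = rng.integers(0, 2, size=(n_recruits, n_loci))
    pick2 = rng.integers(0, 2, size=(n_recruits, n_loci))
    cols = np.arange(n_loci)
    child = np.empty((n_recruits, n_loci, 2), dtype=parents_geno.dtype)
    child[:, :, 0] = parents_geno[p1[:, None], cols[None, :], pick1]
    child[:, :, 1] = parents_geno[p2[:, None], cols[None, :], pick2]
    return child


def advance_year(
    state: PopulationState,
    cfg: LifeCycleConfig,
    target_n: int,
    rng: np.random.Generator,
    year: int | None = None,
) -> PopulationState:
    """One yearly cycle: ageing, death, culling to ``target_n``, recruitment.

    Recruits are age 0 and cannot reproduce in their birth year; each
    recruit draws an independent pair of distinct mature parents.
    """
    where = f" at year {year}" if year is not None else ""
    if cfg.wright_fisher:
        if state.size < 2:
            raise RuntimeError(f"fewer than 2 individuals{where}")
        child = _recruit(state.genotypes, target_n, rng)
        return PopulationState(loci=state.loci, genotypes=child,
                               ages=np.zeros(target_n, dtype=np.int64))

    ages = state.ages + 1
    # mature individuals reproduce in the year they die, so the parent
    # pool is fixed before mortality is applied
    parent_pool = state.genotypes[ages >= cfg.maturity_age]
    alive = ages <= cfg.longevity
    genotypes = state.genotypes[alive]
    ages = ages[alive]
    if len(ages) > target_n:  # bottleneck year: cull uniformly
        keep = rng.choice(len(ages), size=target_n, replace=False)
        genotypes, ages = genotypes[keep], ages[keep]
    n_recruits = target_n - len(ages)
    if n_recruits > 0:
        if len(parent_pool) < 2:
            raise RuntimeError(f"fewer than 2 mature individuals{where}")
        child = _recruit(parent_pool, n_recruits, rng)
        genotypes = np.concatenate([genotypes, child])
        ages = np.concatenate([ages, np.zeros(n_recruits, dtype=np.int64)])
    return PopulationState(loci=state.loci, genotypes=genotypes, ages=ages)


def run_scenario(
    scenario: BottleneckScenario,
    cfg: LifeCycleConfig,
    source: GenotypeDataset | AlleleFrequencyTable,
    replicates: int = 1000,
    seed: int = 0,
    keep_replicate_metrics: bool = False,
    keep_final_states: bool = False,
) -> TrajectorySummary:
    """Replicated forward simulation of one bottleneck scenario.

    Replicate ``r`` uses an RNG stream derived from ``(seed, r)`` so runs
    are reproducible and replicates independent.  Returns yearly means
    and standard deviations over replicates of N_A, A_E, H_E and H_O.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    n_years = scenario.years
    traj = np.empty((replicates, n_years + 1, len(METRICS)))
    finals: list[PopulationState] = []
    for r in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        state = initialize_population(source, scenario.n0, cfg, rng)
        traj[r, 0] = [state.metrics()[m] for m in METRICS]
        for year in range(1, n_years + 1):
            state = advance_year(state, cfg, scenario.target_size(year), rng,
                                 year=year)
            traj[r, year] = [state.metrics()[m] for m in METRICS]
        if keep_final_states:
            finals.append(state)
    years = np.arange(n_years + 1)
    mean = pd.DataFrame(traj.mean(axis=0), index=years, columns=list(METRICS))
    sd = pd.DataFrame(traj.std(axis=0, ddof=1) if replicates > 1
                      else np.zeros_like(traj[0]), index=years,
                      columns=list(METRICS))
    mean.index.name = sd.index.name = "year"
    return TrajectorySummary(
        years=years, mean=mean, sd=sd, replicates=replicates,
        per_replicate=traj if keep_replicate_metrics else None,
        final_states=finals,
    )


def simulate_population(
    scenario: BottleneckScenario,
    cfg: LifeCycleConfig,
    source: GenotypeDataset | AlleleFrequencyTable,
    seed: int = 0,
    replicate: int = 0,
) -> PopulationState:
    """Single replicate run returning the final-year population state."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, replicate)))
    state = initialize_population(source, scenario.n0, cfg, rng)
    for year in range(1, scenario.years + 1):
        state = advance_year(state, cfg, scenario.target_size(year), rng, year=year)
    return state
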