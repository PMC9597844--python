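"""Synthetic microsatellite baselines emulating a small-sample limpet survey.

The generator produces a single-pool allele-frequency baseline with the
structure of the empirical marker panel this package was designed
around: 8 microsatellite loci carrying 84 alleles in total, allele sizes
consistent with di-/tetranucleotide repeat motifs, and a mean expected
heterozygosity around 0.62 (per-locus values kept inside 0.4-0.8).
From that baseline it can sample a "null" metapopulation — many small
populations drawn from identical frequencies, i.e. zero true
differentiation — and bottlenecked/unbottlenecked population pairs via
the forward simulator.  Every draw is deterministic under its seed and
the true baseline frequencies are retained as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import forward_sim
from .diversity import expected_heterozygosity
from .divergence_sim import sample_genotypes
from .genepop import AlleleFrequencyTable, GenotypeDataset

__all__ = [
    "SyntheticSpec",
    "generate_baseline",
    "generate_null_metapopulation",
    "draw_population_sizes",
    "generate_bottlenecked_pair",
]

# Empirical-panel defaults: motif length (bp) and lower end of the allele
# size range for each of the 8 loci; one locus is a tetranucleotide.
_MOTIFS = (2, 2, 2, 2, 4, 2, 2, 2)
_MIN_SIZES = (123, 188, 386, 143, 312, 225, 90, 124)

# Sampling-intensity distribution of the emulated survey: sizes 8-16
# individuals with mean ~9.36.
_SIZE_VALUES = np.arange(8, 17)
_SIZE_PROBS = np.array([0.50, 0.20, 0.10, 0.07, 0.05, 0.03, 0.02, 0.01, 0.02])


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape parameters of the synthetic baseline."""

    n_loci: int = 8
    total_alleles: int = 84
    target_he: float = 0.62
    he_range: tuple[float, float] = (0.4, 0.8)
    he_tolerance: float = 0.05
    n_pops: int = 14
    motif_lengths: tuple[int, ...] = _MOTIFS
    min_sizes: tuple[int, ...] = _MIN_SIZES

    def __post_init__(self) -> None:
        if self.total_alleles < 2 * self.n_loci:
            raise ValueError("need at least 2 alleles per locus")
        if len(self.motif_lengths) < self.n_loci or len(self.min_sizes) < self.n_loci:
            raise ValueError("motif/size tables shorter than n_loci")
        lo, hi = self.he_range
        if not 0 <= lo < hi <= 1:
            raise ValueError("invalid H_E range")


def _allele_counts_per_locus(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Random composition of the allele total over loci (each locus >= 2).

    Allele sizes must stay 3-digit encodable, which caps the count at
    loci with large minimum sizes.
    """
    caps = np.array([
        (999 - spec.min_sizes[l]) // spec.motif_lengths[l] + 1
        for l in range(spec.n_loci)
    ])
    extra = spec.total_alleles - 2 * spec.n_loci
    for _ in range(1000):
        counts = 2 + rng.multinomial(extra, np.ones(spec.n_loci) / spec.n_loci)
        if np.all(counts <= caps):
            return counts
    raise ValueError("infeasible allele-count specification")


def _tune_he(p0: np.ndarray, target: float, tol: float = 1e-9) -> np.ndarray:
    """Deterministically deform a frequency vector to a target H_E.

    Mixes the draw either toward the uniform vector (raising H_E toward
    1 - 1/k) or toward a point mass on its modal allele (lowering it
    toward 0) and bisects the mixing weight.
    """
    k = p0.size
    he0 = expected_heterozygosity(p0)
    if abs(he0 - target) < tol:
        return p0
    if target > he0:
        anchor = np.full(k, 1.0 / k)
        if target > 1 - 1.0 / k:
            raise ValueError(f"H_E={target} unreachable with {k} alleles")
    else:
        anchor = np.zeros(k)
        anchor[np.argmax(p0)] = 1.0
    lo, hi = 0.0, 1.0
    for _ in range(80):
        lam = (lo + hi) / 2
        p = (1 - lam) * p0 + lam * anchor
        he = expected_heterozygosity(p)
        if (he < target) == (he0 < target):
            lo = lam
        else:
            hi = lam
    return (1 - (lo + hi) / 2) * p0 + (lo + hi) / 2 * anchor


def generate_baseline(
    spec: SyntheticSpec = SyntheticSpec(), seed: int | np.random.Generator = 0
) -> AlleleFrequencyTable:
    """Single-pool baseline frequency table under the given spec.

    Per-locus frequencies are symmetric-Dirichlet draws deformed to hit
    per-locus H_E targets scattered around ``target_he``; the realized
    mean H_E is guaranteed within ``he_tolerance`` of the target.
    """
    rng = np.random.default_rng(seed)
    counts = _allele_counts_per_locus(spec, rng)
    lo, hi = spec.he_range
    loci = [f"L{l + 1}" for l in range(spec.n_loci)]
    freqs: dict[str, dict[int, float]] = {}
    spread = min(spec.target_he - lo, hi - spec.target_he, 0.07)
    targets = spec.target_he + rng.uniform(-spread, spread, size=spec.n_loci)
    targets += spec.target_he - targets.mean()  # center the mean exactly
    targets = np.clip(targets, lo, hi)
    for l, locus in enumerate(loci):
        k = int(counts[l])
        sizes = spec.min_sizes[l] + spec.motif_lengths[l] * np.arange(k)
        target = min(targets[l], 1 - 1.0 / k - 1e-6)
        p = _tune_he(rng.dirichlet(np.full(k, 0.8)), target)
        freqs[locus] = {int(s): float(x) for s, x in zip(sizes, p)}
    table = AlleleFrequencyTable.single_pool(loci, freqs, label="baseline")
    realized = np.mean([
        expected_heterozygosity(table.freqs["baseline"][locus]) for locus in loci
    ])
    if abs(realized - spec.target_he) > spec.he_tolerance:
        raise RuntimeError(
            f"realized mean H_E {realized:.3f} misses target {spec.target_he}"
        )
    return table


def draw_population_sizes(
    n_pops: int, rng: int | np.random.Generator = 0
) -> list[int]:
    """Per-population sample sizes mimicking the emulated survey (8-16)."""
    rng = np.random.default_rng(rng)
    return [int(s) for s in rng.choice(_SIZE_VALUES, size=n_pops, p=_SIZE_PROBS)]


def generate_null_metapopulation(
    baseline: AlleleFrequencyTable,
    n_pops: int = 14,
    sizes: Sequence[int] | int | None = None,
    seed: int | np.random.Generator = 0,
) -> GenotypeDataset:
    """Sample ``n_pops`` populations from one shared baseline (true F_ST = 0)."""
    rng = np.random.default_rng(seed)
    if sizes is None:
        sizes = draw_population_sizes(n_pops, rng)
    elif isinstance(sizes, int):
        sizes = [sizes] * n_pops
    elif len(sizes) != n_pops:
        raise ValueError("one size per population required")
    pool = baseline.populations[0]
    labels = [f"pop_{i + 1}" for i in range(n_pops)]
    table = AlleleFrequencyTable(
        loci=list(baseline.loci),
        freqs={lab: baseline.freqs[pool] for lab in labels},
        n={lab: baseline.n[pool] for lab in labels},
    )
    return sample_genotypes(table, {lab: s for lab, s in zip(labels, sizes)}, rng)


def generate_bottlenecked_pair(
    spec: SyntheticSpec = SyntheticSpec(),
    ne_large: int = 500,
    ne_small: int = 50,
    years: int = 100,
    seed: int = 0,
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """One unbottlenecked and one bottlenecked population at the final year.

    Both replicates are founded from the same synthetic baseline; the
    first keeps ``ne_large`` throughout, the second crashes to
    ``ne_small`` after year 1.
    """
    baseline = generate_baseline(spec, seed)
    cfg = forward_sim.LifeCycleConfig()
    big = forward_sim.simulate_population(
        forward_sim.BottleneckScenario(n0=ne_large, n_post=ne_large, years=years),
        cfg, baseline, seed=seed, replicate=0,
    )
    small = forward_sim.simulate_population(
        forward_sim.BottleneckScenario(n0=ne_large, n_post=ne_small, years=years),
        cfg, baseline, seed=seed, replicate=1,
    )
    return big.to_dataset("large"), small.to_dataset("small")
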