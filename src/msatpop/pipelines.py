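"""Experiment pipelines: rarefaction curves and power grids.

Two resampling experiments are wired together here from the lower-level
modules:

* ``subsample_richness`` — how the mean allelic richness of one
  population grows with the number of sampled individuals.  At each
  sampling level S the population is resampled with replacement 100
  times; each resample is standardized to g = 2S gene copies so levels
  are comparable, and the band reported is the 2.5-97.5 percentile range
  of the resample values.
* ``power_drift`` / ``power_island`` — the fraction of simulation
  replicates in which the Fisher-combined multi-locus genic test detects
  differentiation, per scenario cell.  Drift cells are indexed both by
  the generative knob (t) and by the realized mean theta / G'_ST so
  power can be read against measured divergence; at zero divergence the
  power estimate is the alpha error.

All pipelines thread a single integer seed through every random draw and
are deterministic end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .differentiation import differentiation, genic_test_global
from .diversity import allelic_richness
from .divergence_sim import (
    IslandScenario,
    drift_populations,
    island_model_sim,
    sample_genotypes,
)
from .genepop import MISSING, AlleleFrequencyTable, GenotypeDataset

__all__ = [
    "subsample_richness",
    "power_drift",
    "power_island",
    "DEFAULT_LEVELS",
]

#: Sampling-intensity levels of the rarefaction experiment (individuals).
DEFAULT_LEVELS = tuple(range(4, 49, 2))


def _resample_richness(arr: np.ndarray, s: int, reps: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Mean-over-loci allelic richness of ``reps`` with-replacement resamples."""
    n, n_loci, _ = arr.shape
    out = np.empty(reps)
    for b in range(reps):
        idx = rng.integers(0, n, size=s)
        sub = arr[idx]
        vals = []
        for l in range(n_loci):
            copies = sub[:, l, :].ravel()
            copies = copies[copies != MISSING]
            if copies.size == 0:
                continue
            counts = np.bincount(copies)
            counts = counts[counts > 0]
            g = min(2 * s, copies.size)
            vals.append(allelic_richness(counts, g))
        out[b] = np.mean(vals)
    return out


def subsample_richness(
    source: GenotypeDataset | np.ndarray,
    population: str | None = None,
    levels: Sequence[int] = DEFAULT_LEVELS,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    reference_s: int = 50,
) -> pd.DataFrame:
    """Allelic-richness accumulation curve for one population.

    Returns a DataFrame indexed by sampling level with columns ``mean``,
    ``ci_lo``, ``ci_hi`` (percentile band over ``reps`` resamples);
    ``attrs["reference"]`` holds the mean value at ``reference_s``
    individuals, the conventional asymptote proxy.
    """
    if isinstance(source, GenotypeDataset):
        population = population or source.populations[0]
        arr = source.genotypes[population]
    else:
        arr = np.asarray(source)
    levels = list(levels)
    if not levels:
        raise ValueError("no sampling levels given")
    if len(arr) < 2:
        raise ValueError("population must have at least 2 individuals")
    rng = np.random.default_rng(seed)
    rows = {}
    for s in levels:
        vals = _resample_richness(arr, int(s), reps, rng)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        rows[int(s)] = {"mean": vals.mean(), "ci_lo": lo, "ci_hi": hi}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "sample_size"
    ref = _resample_richness(arr, reference_s, reps, rng)
    df.attrs["reference"] = float(ref.mean())
    df.attrs["reference_s"] = reference_s
    df.attrs["n_resamples"] = reps
    return df


@dataclass
class _CellResult:
    power: float
    mean_theta: float
    mean_gprime: float
    replicates: int


def _power_cell(
    datasets,
    alpha: float,
    method: str,
    mc_reps: int,
    rng: np.random.Generator,
    stat_every: int,
) -> _CellResult:
    hits = 0
    thetas, gprimes = [], []
    n = 0
    for i, ds in enumerate(datasets):
        res = genic_test_global(ds, method=method, mc_reps=mc_reps, seed=rng)
        hits += res.p_global < alpha
        if i % stat_every == 0:
            est = differentiation(ds)
            thetas.append(est.theta)
            gprimes.append(est.gprime_st)
        n += 1
    return _CellResult(
        power=hits / n,
        mean_theta=float(np.nanmean(thetas)),
        mean_gprime=float(np.nanmean(gprimes)),
        replicates=n,
    )


def power_drift(
    baseline: AlleleFrequencyTable,
    t_grid: Sequence[int] = (0, 2, 5, 10, 15, 20, 50, 102),
    s_grid: Sequence[int] = (10, 20, 30, 50),
    ne: int = 1000,
    n_pops: int = 14,
    replicates: int = 1000,
    alpha: float = 0.05,
    method: str = "chi2",
    mc_reps: int = 10_000,
    seed: int = 0,
    sizes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Power surface of the differentiation test under drift-only divergence.

    For each cell (t, S): ``replicates`` times, drift ``n_pops``
    populations for t generations at size ``ne``, sample S diploids per
    population, and run the combined genic test.  ``sizes`` (one entry
    per population) replaces a scalar S to emulate an uneven empirical
    sampling design; use ``s_grid=("empirical",)`` with it.

    Returns one row per cell with power, expected F_ST and the realized
    mean theta and G'_ST over (a subsample of) replicates.
    """
    if not t_grid or not s_grid:
        raise ValueError("empty scenario grid")
    from .divergence_sim import expected_fst  # local to avoid cycle at import

    rows = []
    stat_every = max(1, replicates // 100)
    for t in t_grid:
        for s in s_grid:
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, int(t), 0 if s == "empirical" else int(s)))
            )

            def cell_datasets():
                for _ in range(replicates):
                    drifted = drift_populations(baseline, n_pops, ne, int(t), rng)
                    if s == "empirical":
                        smap = {p: sz for p, sz in
                                zip(drifted.populations, sizes)}
                        yield sample_genotypes(drifted, smap, rng)
                    else:
                        yield sample_genotypes(drifted, int(s), rng)

            cell = _power_cell(cell_datasets(), alpha, method, mc_reps, rng,
                               stat_every)
            rows.append({
                "t": int(t), "s": s, "ne": ne,
                "expected_fst": expected_fst(ne, int(t)),
                "power": cell.power,
                "mean_theta": cell.mean_theta,
                "mean_gprime_st": cell.mean_gprime,
                "replicates": cell.replicates,
                "alpha": alpha, "method": method,
            })
    return pd.DataFrame(rows)


def power_island(
    ne_grid: Sequence[int] = (50, 100, 500, 1000),
    m_grid: Sequence[float] = (0.001, 0.005, 0.01, 0.05, 0.1),
    s_grid: Sequence[int] = (10, 20, 30, 50),
    n_demes: int = 10,
    n_loci: int = 8,
    mu: float = 5e-4,
    replicates: int = 1000,
    alpha: float = 0.05,
    method: str = "chi2",
    mc_reps: int = 10_000,
    burn_in: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Power surface under the symmetric finite island model.

    The full default grid is the 4 x 5 x 3(+1) scenario set; every cell
    reports power and the realized mean theta at sampling time.
    """
    rows = []
    stat_every = max(1, replicates // 100)
    for ne in ne_grid:
        for m in m_grid:
            for s in s_grid:
                scenario = IslandScenario(
                    n_demes=n_demes, ne=int(ne), m=float(m), n_loci=n_loci,
                    mu=mu, s=int(s), burn_in=burn_in,
                )
                rng = np.random.default_rng(
                    np.random.SeedSequence((seed, int(ne), int(round(m * 1e6)),
                                            int(s)))
                )
                datasets = (island_model_sim(scenario, rng)
                            for _ in range(replicates))
                cell = _power_cell(datasets, alpha, method, mc_reps, rng,
                                   stat_every)
                rows.append({
                    "ne": int(ne), "m": float(m), "s": int(s),
                    "power": cell.power,
                    "mean_theta": cell.mean_theta,
                    "mean_gprime_st": cell.mean_gprime,
                    "replicates": cell.replicates,
                    "alpha": alpha, "method": method,
                })
    return pd.DataFrame(rows)
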