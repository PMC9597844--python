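# msatpop

Microsatellite population-genetics toolkit for studying **how sample
size affects genetic inference** in small, hard-to-sample populations —
the situation typical of endangered marine invertebrates, where 8–16
individuals per site is often all that can be collected.

It is aimed at conservation-genetics practitioners who need to answer
two questions before (or after) committing to a sampling design:

1. how biased are within-population diversity metrics — number of
   alleles, rarefied allelic richness A_R, effective alleles A_E, H_E,
   H_O, unbiased uH_E, F_IS — at a given sample size S, and
2. what is the statistical power to detect population differentiation
   at a given divergence level with N populations of S individuals?

## What is inside

* **`msatpop.genepop`** — diploid genotype data model with faithful
  Genepop text I/O (2- and 3-digit encodings, missing data, round-trip
  identity).
* **`msatpop.diversity`** — the Table-of-summary-statistics metric set,
  with exact hypergeometric rarefaction
  `A_R(g) = Σ_i [1 − C(N−N_i, g)/C(N, g)]`.
* **`msatpop.differentiation`** — Weir–Cockerham θ (variance components
  a, b, c summed over alleles and loci), Nei G_ST and Hedrick's
  standardized `G'_ST = G_ST (k−1+H_S)/((k−1)(1−H_S))` with Nei–Chesser
  small-sample corrections, bias-recentred bootstrap CIs, Monte-Carlo
  exact genic tests, Fisher's method with a 1e-4 single-locus floor, and
  the Narum α/H_k multiple-testing adjustment.
* **`msatpop.forward_sim`** — forward-time bottleneck simulator with
  overlapping generations (20-year lifespan, maturity at 2, monoecious
  mating without selfing); a `longevity=0` switch gives discrete
  Wright–Fisher generations for validation against
  `H_t = H_0 (1 − 1/(2N))^t`.
* **`msatpop.divergence_sim`** — drift-only divergence from a baseline
  (expected `F_ST = 1 − (1 − 1/(2Ne))^t`) and a symmetric finite island
  model with stepwise mutation.
* **`msatpop.pipelines`** — allelic-richness accumulation curves
  (resampling with replacement, percentile bands) and power grids over
  divergence × sample size or Ne × m × S.
* **`msatpop.synthetic`** — a generator for realistic baselines: 8 loci,
  84 alleles, mean H_E ≈ 0.62, 14 populations of 8–16 individuals.

## Worked example

```python
import msatpop as mp

base = mp.generate_baseline(seed=1)                 # 8 loci, 84 alleles
ds = mp.generate_null_metapopulation(base, 4, [12, 10, 9, 14], seed=5)

df = mp.summarize(ds)                               # Table-2-style summary
print(df[["n_alleles", "allelic_richness", "exp_het", "obs_het", "f_is"]].round(3))

res = mp.differentiation(ds)
lo, hi = mp.bootstrap_ci(ds, "theta", reps=1000, seed=3)
test = mp.genic_test_global(ds, method="fisher_mc", mc_reps=10000, seed=3)
print(f"theta={res.theta:.4f}  CI=({lo:.4f}, {hi:.4f})  G'ST={res.gprime_st:.4f}  p={test.p_global:.3f}")
```

prints

```
            n_alleles  allelic_richness  exp_het  obs_het   f_is
population
pop_1           5.750             5.019    0.532    0.583 -0.080
pop_2           5.375             5.155    0.591    0.638 -0.086
pop_3           5.000             5.000    0.542    0.597 -0.089
pop_4           6.250             5.104    0.566    0.598 -0.058
theta=-0.0040  CI=(-0.0272, 0.0269)  G'ST=-0.0088  p=0.591
```

All four pseudo-populations were drawn from the *same* baseline, and the
numbers say exactly that: moderate heterozygosity (H_E ≈ 0.53–0.59), a
slight heterozygote excess (negative F_IS), a θ estimate that is
indistinguishable from zero with a bootstrap CI spanning zero, and a
non-significant global exact test.  Rarefied richness (here standardized
to g = 18 gene copies) is the column to compare across populations of
unequal size.

The same machinery runs from the shell: `msatpop stats`, `diff`,
`bottleneck`, `subsample`, `power-drift`, `power-island` and `gen-synth`
(see `msatpop --help`); every run echoes its seed and parameters and is
byte-reproducible.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch on a freshly generated synthetic baseline:

* **t1** — the α error of the global differentiation test (Fisher-combined
  per-locus Monte-Carlo exact tests) over 500 null datasets of 14
  populations × 10 individuals;
* **t8** — the power (%) of the χ² differentiation test at S=30 under
  drift-only divergence at the 0.0025 divergence level (Ne=1000);
* **t9** — the power (%) of both χ² and Monte-Carlo exact variants at
  S=50 at the 0.001 divergence level.

Each entry in the JSON output carries the computed value and the number
of replicates behind it; the run takes ~5 minutes on one CPU.
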