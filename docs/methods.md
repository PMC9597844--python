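# Methods

`msatpop` studies one question: how does the number of individuals
sampled per population (S) bias microsatellite diversity metrics and the
power to detect population differentiation?  It packages the estimators,
the simulators that generate populations with known properties, and the
resampling pipelines that connect the two.  This note records the models,
the parameter choices, and the numerical decisions, in that order.

## Estimators

**Within-population diversity** (module `diversity`).  For a locus with
sample allele frequencies `p_i` and `N` genotyped individuals:

* expected heterozygosity `H_E = 1 − Σ p_i²` and Nei's unbiased version
  `uH_E = 2N/(2N−1) · H_E`;
* observed heterozygosity `H_O` = fraction of non-missing calls whose two
  alleles differ;
* effective number of alleles `A_E = 1/Σ p_i²` (so `H_E = 1 − 1/A_E`
  identically);
* allelic richness `A_R(g) = Σ_i [1 − C(N_c − N_i, g)/C(N_c, g)]`, the
  exact hypergeometric expectation of the allele count in a subsample of
  `g` gene copies (`N_c` total copies, `N_i` copies of allele i),
  evaluated with log-gamma binomials so totals in the thousands are safe;
* inbreeding coefficient `F_IS = 1 − H_O/H_E`, undefined (and excluded
  from population means) at monomorphic loci.

Population summaries report the mean over loci ± SE, with SE the sample
standard deviation over loci (denominator L−1) divided by √L.  The
default rarefaction size is the smallest per-locus gene-copy count over
the populations being compared, accounting for missing data; missing
calls are dropped locus-wise.

**Between-population differentiation** (module `differentiation`).
Weir–Cockerham θ is computed from the a/b/c variance components summed
over alleles and loci; the multilocus estimate is the ratio of summed
components (never a mean of per-locus ratios) and negative values are
preserved — they are informative about undifferentiated samples.  Nei's
`G_ST = (H_T − H_S)/H_T` and Hedrick's standardized
`G'_ST = G_ST (k−1+H_S)/((k−1)(1−H_S))` are available in two forms: a raw
frequency-parameter version (used for hand-checkable examples and
true-frequency diagnostics) and the dataset-level version with the
Nei–Chesser small-sample corrections (harmonic-mean sample size and
observed-heterozygosity terms), with `H_S` and `H_T` averaged over loci
before forming ratios.

**Significance tests.**  Per-locus tests act on the allele × population
gene-copy table: an asymptotic Pearson χ² or a Monte-Carlo exact test
that permutes pooled gene copies among populations with fixed margins
and scores tables by conditional probability, with
`p = (1 + #{P_sim ≤ P_obs})/(reps + 1)` so p is never 0.  Multi-locus
combination deliberately differs between the two arms, matching the two
tool conventions this workflow descends from: the χ² arm sums statistics
and degrees of freedom over loci, while the exact arm combines p-values
with Fisher's method (`−2Σln p`, df = 2L) after flooring each per-locus
p at 1e-4 so a single locus cannot dominate.  Multiple testing over
population pairs uses the Narum adjustment `α/H_k` (harmonic number of
the number of pairs): `H_91` gives adjusted α ≈ 0.0098 for 14
populations.

**Bootstrap CIs.**  Confidence intervals for θ and `G'_ST` resample
individuals with replacement within populations.  A plain percentile
interval is biased here: duplicated individuals inflate the resampled
estimator by O(1/S), and with S ≈ 10 the null interval excludes zero
(measured ≈ [0.03, 0.06] around a point estimate of −0.008).  The
interval is therefore recentred on the point estimate (shifted by
θ̂ − mean θ*), which restores near-nominal null coverage (30/30 null
datasets covered 0 in the test suite) while keeping individuals as the
resampling unit.

## Simulators

**Bottleneck model** (module `forward_sim`).  An isolated, constant-size,
monoecious population with overlapping generations: maximum lifespan 20
years (a hard age cap, not an exponential survival — deterministic death
rule), maturity at 2 years, founders given uniform random ages
(fully-overlapping age structure), random mating without selfing, no
mutation/migration/selection.  The yearly cycle is: age; fix the mature
parent pool; apply mortality; cull uniformly to the target size if above
it (the bottleneck year); recruit age-0 offspring from independent
distinct-parent pairs until the target size is restored.  Parents are
drawn before mortality so a cohort that dies this year still reproduces
— this is what keeps the degenerate all-at-maximum-age case well
defined.  Census size is equated with N_e because scenarios are
parameterised directly in N_e.  The default scenario set starts at
N_e = 500 and drops to 500/100/50 after year 1, running 100 years.
Setting `longevity = 0` switches to discrete generations (the whole
population is replaced each step), which reproduces Wright–Fisher
heterozygosity decay `H_t = H_0(1 − 1/(2N))^t` to ~0.1% at N=50, t=20 —
the simulator's validation oracle.  Excluding selfing alters the decay
rate by O(1/N²), far below the 5% test tolerance.

**Drift-only divergence** (module `divergence_sim`).  Populations start
from a shared baseline frequency table and drift independently via
multinomial resampling of 2N_e gene copies per locus per generation;
samples of S diploids are drawn from the drifted frequencies under HWE.
Expected divergence is `F_ST = 1 − (1 − 1/(2N_e))^t`; realized
multilocus θ matches this within 1–2% at N_e = 1000 over the t grid.
Divergence *levels* (0.001, 0.0025, …) are mapped to integer t through
this closed form.  The realized Hedrick `G'_ST` at those t is ≈2.8×
larger than the nominal level (the `(k−1+H_S)/((k−1)(1−H_S))` inflation
at H_S ≈ 0.62, k=14), so power results are indexed by both the nominal
level and the realized mean θ/G'_ST rather than assuming the two scales
coincide.

**Finite island model.**  n demes (default 10) of N_e diploids exchange
gametes symmetrically: each gene copy of the next generation immigrates
with probability m from a uniformly chosen other deme, then picks a
random parent copy there.  Mutation is strict stepwise (±1 repeat unit,
reflecting at repeat counts 5 and 60; the loci emulated are di- and
tetranucleotide microsatellites), at rate μ = 5e-4 per copy per
generation by default.  Demes start from an identical maximally mixed
pool of 10 central repeat states; burn-in defaults to 10 N_e
generations with an F_ST monitor that records a non-convergence warning
if the last two monitoring windows differ by >10% (suppressed below
F_ST = 0.01, where relative trends are noise).  With μ ≈ 0 the realized
equilibrium θ at N_e=100, m=0.01 is ≈0.18 against the classical
`1/(1 + 4 N_e m (n/(n−1))²) = 0.168`; with m = 0 a single deme reaches
the stepwise-mutation heterozygosity `1 − 1/√(1 + 8 N_e μ)` within the
20% test tolerance.  The migration correction `(n/(n−1))²` is emergent,
not imposed.

## Synthetic baseline

The generator emulates the empirical survey structure this analysis was
designed around: 8 loci carrying 84 alleles in total (random composition
with ≥2 per locus, capped so 3-digit Genepop encoding always suffices),
allele sizes on di-/tetranucleotide ladders within realistic size
ranges, 14 populations with sample sizes 8–16 (mean ≈ 9.36), and mean
expected heterozygosity 0.62 with per-locus values in [0.4, 0.8].
Per-locus frequency vectors are symmetric Dirichlet draws
(concentration 0.8) deformed deterministically — bisection on a mixing
weight toward the uniform vector or toward a point mass — until the
per-locus H_E target is hit; the realized mean is guaranteed within
±0.05 of the target.  What the generator does *not* emulate: the exact
empirical per-locus allele-count breakdown and frequency spectrum
(unpublished), linkage, null alleles, genotyping error, or spatial
structure.  A green test on this stated world therefore establishes the
statistical machinery, not the field data; the measured power shortfall
at the weakest divergence level (≈89% vs the reported ≥95% at S=30,
level 0.0025) is consistent with the spectrum sensitivity of genic-test
power at fixed mean H_E.

## Pipelines and numerical choices

* Rarefaction curves resample **individuals with replacement** at each
  sampling level S ∈ {4,…,48} (100 resamples), standardize each resample
  to g = 2S gene copies, and report the mean with a 2.5–97.5 percentile
  band (a percentile band, not mean ± 1.96 SD).
* Power is the fraction of replicates whose global test is significant
  at α = 0.05; at zero divergence it is the α error by construction.
  Cells record realized mean θ and `G'_ST` over a replicate subsample.
* Monte-Carlo exact tests default to 10⁴ permutations in library calls
  and 10⁵ in the CLI `diff` subcommand; reduced-replicate modes are
  first-class flags, with every documented tolerance expressed in
  binomial SEs so scaled-down runs remain valid.
* All randomness flows through `numpy.random.Generator` seeded from a
  single integer; replicate r of any replicated run derives its stream
  from `(seed, r)` so runs are reproducible and parallelizable.
* Degenerate inputs: monomorphic loci contribute zero variance
  components and are excluded from θ ratios; `H_T = 0` flags G-statistics
  as undefined (NaN); all-missing cells are flagged with n = 0;
  rarefaction with g larger than the available gene copies raises an
  error naming the deficient cell.

## Known limitations

* Haploid/polyploid data, SNP/sequence input, HWE/linkage/null-allele
  screening, AMOVA, Jost's D and isolation-by-distance are out of scope.
* The island model uses discrete generations (no overlap) and symmetric
  migration only; the bottleneck model supports a single-step size drop.
* The bootstrap recentring corrects first-order resampling bias but is
  not a BCa interval; very small populations (S < 5) still produce
  unstable intervals.
* Genic χ² p-values rely on asymptotics that are conservative for
  sparse allele × population tables (measured α ≈ 0.03–0.04 at S=10);
  the Monte-Carlo exact test is the calibrated reference (α ≈ 0.05).
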