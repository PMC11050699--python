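# Methods

`bgakit` implements the statistical core of biogeographical-ancestry (BGA)
inference from a small panel of ancestry-informative SNPs (aiSNPs): calling
biallelic genotypes from massively-parallel-sequencing read counts, and
assigning a profile to a reference population by three independent routes —
likelihood ranking, a z-score outlier test, and PCA cluster membership —
with a consensus tabulation over a cohort. A synthetic-data generator
produces every input the pipeline consumes, so the whole chain is testable
without access to human data.

## Genotype model

All predictors share one model: loci are independent and biallelic, and
within a population genotype probabilities follow Hardy–Weinberg
proportions of the designated-allele frequency *p*:

    P(aa) = p²,  P(ab) = 2p(1−p),  P(bb) = (1−p)².

A reference panel stores *p* per population × locus, the population sample
size *N*, and a metapopulation (continental) grouping. Frequencies of
exactly 0 or 1 would make log-likelihoods infinite, so panels are floored
before likelihood work: *p* is clamped to `[f_min, 1−f_min]` with the
pseudo-count rule `f_min = 1/(2N+2)` per population by default (a constant
floor is available). Flooring is idempotent and cannot reorder populations
at a locus except by creating ties at the bounds. Missing (population,
locus) cells are kept as missing and the locus is excluded from every
comparison involving that population — never treated as frequency zero.

Panel QC includes a per-locus Pearson chi-square test of Hardy–Weinberg
proportions (1 df, no continuity correction, allele frequency estimated
from the genotype counts), reported with raw and Bonferroni-adjusted
p-values; monomorphic loci return χ²=0, p=1 with a flag rather than an
error.

## Genotype calling and QC

Calling uses a two-tier threshold scheme standard for forensic MPS panels.
An allele is **detected** iff its reads are at least `analytical_min_reads`
(default 10) *and* at least `analytical_fraction` (default 1.5%) of the
locus's total reads; fractions are always computed against the locus total,
not the major allele. Two detected alleles form a heterozygote, one a
homozygote, none a missing locus (`no_call`). Qualifiers:

* `low_confidence` — a detected allele below the interpretation threshold
  (default 30 reads / 4.5%);
* `dropout_suspected` — a homozygote whose other allele showed 1–9 reads,
  or whose total depth is below `dropout_depth` (default 100 reads; low
  totals are where false homozygotes arise, and raising the usable-depth
  bar to ~100 reads is the natural mitigation for low-input samples);
* `imbalanced` — a heterozygote whose balance is below 0.1.

Heterozygote balance (Hb) is reported in two conventions: the **min-allele**
value `min(r₁,r₂)/(r₁+r₂) ∈ (0, 0.5]` used for flagging, and the
**ordered** value `r₁/(r₁+r₂)` (allele 1 alphabetical) used for
distribution summaries, which spreads symmetrically around the expected
0.5. Flags never suppress a call: retyping or exclusion policy is left to
the caller, and the pipeline's strict mode (default) simply excludes
incomplete profiles from prediction.

Cohort QC aggregates per-locus depth and balance distributions, per-sample
completeness (fraction of panel loci with a call), per-locus drop-out
counts, and success rate (called / expected genotypes) grouped by any
profile attribute — grouping by DNA input yields the sensitivity curve.

## Likelihood ranking

Each population is scored with the profile's log10 likelihood, the sum of
per-locus log genotype probabilities (accumulated in natural log,
converted at the interface, since the decision rule is phrased in orders of
magnitude). All populations are scored on the common locus set — the
profile's called loci typed in *every* scored population — so values are
comparable. Populations within `window_log10` (default 1.0, one order of
magnitude) of the best are statistically indistinguishable and form the
candidate set; the sample is predicted to a metapopulation iff all
candidates share it, else the call is inconclusive. Ties break by
population name for reproducibility. This predictor always ranks: it has
no rejection outcome, so a profile from a population absent from the panel
is still assigned to the least unlikely one — the structural weakness the
z-score test addresses.

## Z-score outlier test

For a hypothesized population, the log-likelihood of a *true member's*
profile has exact per-locus moments

    mu_locus  = Σ_g q_g ln q_g,
    var_locus = Σ_g q_g (ln q_g)² − mu_locus²,

summed over independent loci, and the standardized deviation
`z = (mu − ℓ_obs)/√var` is asymptotically standard normal. One-sided
acceptance at 95% uses the critical value 1.64 (the conventional
two-decimal rounding of Φ⁻¹(0.95); the exact quantile is available via
`ZTestConfig.exact_z_crit`). z is invariant to logarithm base and locus
order. Hypotheses are, by default, metapopulations: pooled frequencies are
the sample-size-weighted mean of member populations, floored after pooling.

Decision rule: no accepted hypothesis → **rejected**; one → **accepted**;
several → the accepted population with the highest observed likelihood must
beat each other accepted one by a log-likelihood-ratio whose 95% confidence
interval excludes zero, `D_obs ± 1.96·√Var_top[d]`, with the per-locus
moments of `d = ln q_top − ln q_other` taken under the top population's
genotype distribution; any interval covering zero → **inconclusive**.
Reference frequencies are treated as known: the variance carries no
finite-*N* correction, a deliberate simplification.

Two numerical facts about this test, both computed by the test suite:

* *Calibration*: at 56 loci the acceptance rate for profiles drawn from the
  hypothesized population itself is ≈94%, not the nominal 95%: the
  log-likelihood sum is left-skewed (rare genotypes contribute large
  negative terms), and the normal approximation undershoots one-sided
  coverage by about one percentage point at this locus count.
* *Conservatism*: the population-level LR interval is wide (half-width
  several orders of magnitude at 56 loci), so moderately diverged
  populations that are co-accepted frequently remain unresolved. Combined
  with the ~6% inherent rejection rate this caps the tool's strict decision
  accuracy well below the ranking tool's on the synthetic panels — the same
  accept/reject trade-off the tool exists to make. The suite's
  parameter-recovery check records this: on the default three-population
  panel the ranking tool's decision accuracy exceeds 90% while the z-score
  tool's falls short of that bar under this LR rule.

A first-generation admixture hypothesis replaces HWE with one allele drawn
at each parent population's frequency — `P(aa) = p_A p_B`,
`P(ab) = p_A(1−p_B) + p_B(1−p_A)`, `P(bb) = (1−p_A)(1−p_B)` — and the same
moment/z machinery applies. With `p_A = p_B` it reduces exactly to the
single-population test.

## PCA assignment

Reference individuals (0/1/2 copies of the designated allele) are
normalised per locus by centring at 2p̂ and scaling by √(p̂(1−p̂)) — the
usual allele-frequency standardisation that equalises drift variance across
loci — and the top two singular directions define the plane (two components
only, matching the 2D plots such tools present). Monomorphic loci are
dropped; missing genotypes are mean-imputed, so an entirely missing profile
projects to the global centroid. Each labelled cluster gets its projected
centroid and 2×2 covariance (ridge-repaired if singular, with a warning).
An unknown is assigned to a cluster when its squared Mahalanobis distance
is within the χ²(2 df) quantile (default 95%); membership in none, in more
than one, or only in a cluster designated as admixed reference is
inconclusive. The ellipse criterion is our choice of a reproducible,
statistically interpretable membership rule where commercial tools leave
"clustered with" undefined. Sign indeterminacy is fixed by making each
component's largest-magnitude loading positive, so output is deterministic.
When only frequencies are available, reference cohorts are simulated from
the panel (default 100 individuals per cluster). A frequency-matrix mode
runs centred PCA on populations × loci for structure plots of the panel
itself.

## Consensus reporting

Decisions are classified against truth labels at the metapopulation level
(population-level scoring is an option): correct, incorrect, inconclusive,
or rejected (z-score tool only). Cohort tables report counts (always
summing to the group size), percentages rounded to one decimal, exact
fraction strings, and the conditional accuracy excluding rejected samples,
which by construction never falls below the unconditional rate when
anything is rejected.

## Synthetic cohorts

The generator emulates the study design the pipeline is meant for:

* **Panel** — Balding–Nichols drift: ancestral frequency p₀ uniform on
  (0.1, 0.9) (common SNPs; panel markers are pre-selected to be
  informative), population frequency ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F), so
  E[p]=p₀ and Var[p]=F·p₀(1−p₀). Defaults: 56 loci, 3 populations, F=0.15
  per population (moderate continental-scale divergence, the condition the
  recovery checks use). F=0 copies p₀ exactly.
* **Individuals** — HWE draws; first-generation admixed individuals draw
  one allele at each parent's frequency (1:1 admixture).
* **Read depths** — negative-binomial total depth with mean
  `depth_mean_at_1ng × efficiency × input_pg/1000` (the linear depth–input
  law seen in dilution series) and dispersion 5 (visible overdispersion
  without pathological zeros); per-locus efficiencies default to 1.0 with
  the first three loci at 0.1× to reproduce the handful of poorly
  amplifying markers that dominate real drop-out; `depth_mean_at_1ng`
  defaults to 1000 reads, placing the poor loci near the ~100-read median
  depth regime where genuine kits struggle. Heterozygote reads split
  Binomial(depth, ½); homozygotes receive Binomial(depth, 0.5%) noise reads
  on the non-carried allele — in expectation below the 1.5% analytical
  threshold, so the threshold logic is exercised without flooding calls.
  Zero depth removes the locus.

Everything is reproducible from a single integer seed.

What the generator deliberately does **not** model: linkage between loci
(the likelihood models assume independence), locus-specific allelic bias,
sequencing error beyond symmetric noise reads, reference-database
misspecification, and the ascertainment that makes real aiSNP panels more
informative per locus than Balding–Nichols drift at the same FST. Passing
tests therefore demonstrate the statistical machinery is correct under its
own assumptions, not that any particular accuracy will be attained on real
casework cohorts.

## Numerical and design choices

* Natural-log accumulation everywhere; log10 only at interfaces.
* Likelihood comparability enforced via the locus-set intersection across
  scored populations; loci untyped in any scored population are dropped for
  all of them.
* `z_crit` fixed at the printed two-decimal 1.64 rather than the exact
  quantile, matching reported tool behaviour; configurable.
* Degenerate cases are defined, not fatal: monomorphic HWE loci flag and
  return χ²=0/p=1; a singular cluster covariance is ridge-repaired;
  `f_min ≥ 0.5`, zero usable loci, all-missing profiles, and >2 detected
  alleles raise errors.
* Problem sizes in the test suite and acceptance script are desk-scale by
  design: 5,000 profiles × 56 loci for z-test calibration, 10,000 draws for
  balance symmetry, 100 profiles per population for recovery checks —
  large enough that Monte-Carlo error is small against every asserted
  tolerance.

## Reproducing the summary numbers

`scripts/acceptance.py --seed S --out results.json` regenerates, from
scratch under seed `S`: the z-test acceptance rate for matched profiles
(5,000 profiles, 56 loci, frequencies uniform on (0.1, 0.9)) and the median
ordered heterozygote balance under unbiased binomial read splits (10,000
loci at depth 300). Expected values are ≈94–95% and 0.5.

## Known limitations

* The z-test variance ignores reference-frequency estimation error; with
  small reference panels the test is anti-conservative.
* The LR-resolution step between co-accepted populations is conservative
  (see above); close populations frequently yield inconclusive rather than
  a forced choice.
* Biallelic SNPs only; no strand/coordinate resolution — allele letters
  must match the panel by rsID exactly.
* PCA assignment depends on the reference cohorts' cluster geometry; with
  simulated reference individuals the ellipses inherit the generator's
  assumptions.
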