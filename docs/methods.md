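# Methods

This note documents the statistical models implemented in `evoherit`, the
assumptions behind the synthetic-data generator, the numerical choices,
and the limits of what passing tests demonstrate.

## The experimental design being modeled

A panel of n_g haploid founders, each a random mosaic of two parental
genomes (RM and BY alleles at m biallelic loci), founds replicate
populations that evolve for a fixed number of generations in one of two
environments: optimal temperature (OT) and high temperature (HT). Fitness
is a per-generation selection coefficient measured by competition against
a common fluorescent reference. The traits of interest are the founder
fitness X (per environment), the fitness increment ΔX of each descendant
population in its home environment (adaptability), and the increment in
the other environment (pleiotropy).

## Variance partitioning (broad-sense heritability)

For founder fitness, total variance is partitioned into measurement error
and genotype:

    σ²_t = (1/n_g) Σᵢ (Xᵢ − X̄)²,   σ²_ε = (1/n_g) Σᵢ σ²_{ε,i},
    σ²_f = σ²_t − σ²_ε,            H² = σ²_f / σ²_t.

σ²_{ε,i} is the error variance of the founder's **mean** fitness — the
unbiased replicate sample variance divided by the replicate count. This
variance-of-the-mean convention is the one under which an H² near 1 is
attainable with few technical replicates; the raw replicate-variance
alternative is exposed via `summarize_replicates(..., of_mean=False)`.

For increments, the noise component pools within-founder spread across
replicate populations with a per-founder small-sample correction:

    σ²_p = (1/n) Σᵢ [n_{p,i}/(n_{p,i}−1)] Σⱼ (ΔXᵢⱼ − ΔX̄ᵢ)²,

and σ²_t is the per-population variance about the grand mean, n the total
population count. Founders contributing a single population are excluded
(σ²_p is inestimable for them) with a warning.

All divisors are population-style 1/n, matching the defining equations
rather than the n−1 sampling convention; at n ≥ 230 the difference is
negligible, and the tests pin the formulas exactly against brute-force
oracles. A negative σ²_f (possible when noise estimates exceed the total)
is reported raw; `H2_clipped` truncates to [0, 1] for summaries.

Confidence intervals use a seeded leave-⌈n/2⌉-out jackknife over founders
with percentile endpoints (default 1000 resamples). The resample count
and the percentile construction are package choices; the delete-d
variance formula would be an alternative but percentiles behave better
for ratio statistics near their [0, 1] boundary.

## Narrow-sense heritability (REML)

Genotypes are standardized per locus, g_{ik} = (aᵢₖ − pₖ)/√(m pₖ(1−pₖ))
with aᵢₖ ∈ {0 = RM, 1 = BY} and pₖ the BY frequency in the analyzed
panel, giving kinship R = GGᵀ with unit average diagonal. The additive
model Y = α + Σₖ gᵢₖaₖ + ε with random effects a ~ N(0, σ²_a),
ε ~ N(0, σ²_e) implies V = Rσ²_a + Iσ²_e. The restricted likelihood (with
an intercept-only fixed effect — the model's only systematic term) is
profiled over the total variance and maximized over the ratio
h = σ²_a/(σ²_a+σ²_e) ∈ [0, 1] by bounded scalar search on the eigenbasis
of R (tolerance 1e−6). Then h² = σ̂²_a / Var(Y) with the n−1 sample
variance. Estimates at the ratio boundary are flagged. When jackknifing,
allele frequencies (hence the standardization) stay fixed from the full
panel: the subset estimates then answer "how variable is h² across
half-panels of *this* cross" rather than re-defining the relatedness each
time.

## QTL mapping

Forward selection with one locus per iteration. At iteration k+1 the
trait is residualized by OLS on the ±1/2 codes of the k detected QTLs;
every locus is scored by the weighted Pearson correlation r between its
code and the residuals (weights default to √(replicate count), kept
attached to the observations while residual values are permuted), giving
LOD = −(n_g/2)·log₁₀(1−r²). The genome-wide maximum is tested against the
permutation distribution of the maximum (one null per iteration), with
p = (1+#{perm max ≥ obs})/(1+n_perm); detection stops at p > α = 0.05 or
at a safety cap of 20 QTLs. Positional confidence intervals take the
maximal contiguous run of loci on the peak chromosome with LOD within 1.5
of the peak; ties at the peak resolve to the lowest locus index. Reported
effects are the coefficients of a final joint OLS over all detected loci.

Monomorphic loci score r² = 0 rather than erroring mid-scan; a scan on a
fully monomorphic panel errors. A trait that is an exact copy of a locus
code yields r² = 1 (infinite LOD); the hit is flagged `perfect_fit` and
the scan stops rather than iterating on a zero residual.

## Adaptability and pleiotropy models

All regressions are ordinary least squares on founder means (the trait is
the mean increment of a founder's replicate populations), fitted via
statsmodels; per-population fitting is possible by passing population
rows directly.

- **Declining adaptability:** ΔX̄ᵢ = α + βXᵢ + εᵢ.
- **Noise robustness:** the measurement error of X also enters ΔX with
  opposite sign and can manufacture correlation; re-adding independent
  N(0, σ²_{ε,i}) noise to Xᵢ over n_draws = 100 seeded draws bounds that
  artifact. The reported mean r² can only be attenuated, never inflated.
- **Pleiotropy:** Δ_away,ᵢ = α + β·X_away,ᵢ + γ·X_home,ᵢ + εᵢ with
  per-coefficient significance; |corr| > 0.999 between predictors is
  flagged as collinear.
- **Combined model:** fitness, the focal-locus indicator g* (±1/2), QTL
  main effects, and g*×QTL interactions. Single-restriction F-tests per
  term are Bonferroni-corrected across all tested non-intercept terms
  (α = 0.05); the model is refit once on the significant terms — no
  stepwise loop. Aliased (duplicate or constant) columns are dropped with
  a warning before fitting.
- **Normalized differences:** traits are centered and scaled by the n−1
  standard deviation per environment (optionally within focal-allele
  strata); the correlation between X̃−Ỹ and ΔX̃−ΔỸ is tested by a
  seeded bootstrap over founders, reporting a one-sided p for r < 0.

## Mutation calling

Site filters run in a fixed order on per-site read-count tables: first
remove sites whose alternate allele is in the majority (strictly > 0.5)
in at least 6 populations, then — on the survivors — sites above 10%
(strict) in 5 or more populations. Cells with zero depth have undefined
frequency and count toward neither threshold. Ties go to retention
(literal readings of "majority" and "above"). Calls require alternate
frequency strictly above 0.5 and at least 4 supporting reads. Identical
SNVs in two or more populations of the same founder are treated as
standing variation and removed from all carriers. Gene assignment uses
1-based inclusive intervals internally (BED input converted at the
boundary); overlapping annotations resolve to the smallest containing
interval. Consequence classes come from the annotation or generator —
codon-level effect prediction is out of scope. A multi-hit gene has
putatively functional calls (missense, putative loss-of-function, or
in-gene indel) in ≥ 2 distinct populations. The expected overlap between
k multi-hit genes and q QTL-interval genes in an N-gene genome is the
hypergeometric mean kq/N, with P(overlap ≥ observed) from the
hypergeometric tail.

## Mutual information

I(W, g | Z) is estimated from observed frequencies in bits, with
0·log 0 := 0 and empty strata skipped at weight 0; the statistic M sums
over a gene universe defaulting to the multi-hit list (genes hit once
carry no association signal but add permutation noise; the full list is
available by passing it explicitly). The permutation null shuffles the
pooled multiset of event gene labels across mutation events, deals each
population its original event count, and re-binarizes — preserving both
per-population counts and the overall gene-label spectrum, so the test
isolates *which populations* got hit, not *how many hits* occurred. The
hierarchical analysis reports M(focal allele), M(environment | focal),
and M(founder | focal, environment), each centered on its null mean.

## The synthetic generator

The generator emulates the design's statistical structure, not its
population dynamics:

- **Genotypes:** each founder's chromosome is a two-state Markov chain —
  first locus RM/BY at 1/2, switch probability per interval (default
  0.05, 16 chromosomes × 75 loci) — i.e. recombination without
  interference. Only linkage decay matters downstream.
- **Founder fitness:** additive QTL effects on ±1/2 codes (BY positive)
  plus optional pairwise epistasis and Gaussian residual. The default
  layout plants one large-effect focal locus (+0.09 at OT, +0.19 at HT,
  the BY−RM difference) and five smaller shared QTLs, with residual s.d.
  chosen so the planted QTLs explain ≈ 76% of fitness variance in each
  environment.
- **Evolution:** ΔX_home = a + b·X_home + uᵢ + eᵢⱼ with founder-level
  deviation uᵢ (s.d. 0.018) and population noise eᵢⱼ (s.d. 0.029 at OT,
  0.046 at HT); slope b = −0.5 in both environments. Away increments
  follow the away environment's own (damped) rule, with deviations and
  noise correlated ρ = 0.5 with the home draws — the home–away
  correlation structure is a free parameter of the design, not something
  the analysis pins down, so it is exposed in the config. These defaults
  put the generative broad-sense heritability of measured increments at
  0.62 (OT) and 0.65 (HT).
- **Mutations:** per-population counts are Poisson with mean
  max(0, λ_env + c·X_home) (λ = 1.3 at OT, 3.6 at HT, c = −3 per unit
  fitness — the flooring keeps the mean admissible); gene labels draw
  uniformly from target sets conditioned on the focal allele and
  environment (a ribosome-biogenesis-like class reachable only from the
  RM allele, a cAMP-like class only from BY, two HT-only genes, and a
  shared pool).
- **Measurement:** Gaussian error (s.d. 0.01 per environment), 4
  technical replicates per founder and 1 per evolved population; optional
  competition-count quadruples invert the fitness estimator exactly for
  round-trip tests.

One RNG seeds the whole dataset through named substreams (genotypes /
fitness / evolution / measurement), so each stage is independently
reproducible and identical configs produce byte-identical tables.

What the generator does **not** emulate: clonal interference and lineage
dynamics (increments are drawn from the phenomenological rule), linkage
between real marker maps and real recombination hotspots, non-Gaussian
measurement error, batch effects, or sequencing noise beyond binomial
read sampling in the site-count synthesizer. Parameter-recovery tests
therefore show that the estimators are correct under the model the
analysis assumes — they do not certify behaviour under model violations
real data may contain.

## Problem sizes and numerical choices

The test suite and the acceptance script run the estimators at the
design's native scale (230 founders, 4 populations per founder per
environment) wherever the claim depends on it, with reduced marker maps
(200–1000 loci) where only effect sizes, not map density, drive the
statistic, and permutation/bootstrap counts of 200–2000 chosen so
Monte-Carlo error is small relative to the tested tolerances. Defaults in
the package are larger (n_perm = 1000 for QTL scans, 10 000 for the MI
null and bootstrap CIs). Permutation p-values use the +1 correction and
are therefore never exactly zero. REML tolerances: 1e−6 on the variance
ratio; eigenvalues clipped at zero for numerical negatives.

## Known limitations

- The increment partition assumes within-founder population spread is
  exchangeable across founders; systematic heteroskedasticity (e.g.
  fitness-dependent stochasticity) biases σ²_p.
- REML uses a single kinship matrix; shared environmental structure
  between related founders would inflate h².
- Forward QTL selection inherits the usual winner's-curse bias in effect
  sizes at detected loci; confidence intervals are positional, not
  effect-size intervals.
- The MI statistic binarizes incidence; recurrent hits of the same gene
  within one population carry no extra weight.
- With very few mutation events the permutation null becomes discrete
  and conservative.
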