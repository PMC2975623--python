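# Methods

This note documents the models behind `rareweight`, the defaults and the
reasoning for them, the numerical choices, and what the simulation design
can and cannot say about real data.

## Demographic model and site-frequency simulation

Allele frequencies of nonsynonymous sites in one gene evolve neutrally
under a three-epoch history of the European population: a constant
ancestral diploid size `N1`, an instantaneous bottleneck to `Nb`, and
exponential growth at rate `rho` per generation for `T` generations to the
present.  Defaults `N1 = 20,000`, `Nb = 14,000`, `T = 3,300`,
`rho = 0.001` imply a present-day effective size `Nb·e^(rho·T) ≈ 380,000`
and, at 20 years per generation, a bottleneck about 66,000 years ago.
Time is indexed in generations before present; `g = 0` is the present and
`g = T` the bottleneck instant.

The engine is a forward-in-time Wright–Fisher simulation: per-site
derived-allele counts are binomially resampled each generation into the
next generation's chromosome pool, and new mutations enter as singletons
at total rate `2·N(g)·mu_nt·L·(1 − syn_fraction)` per generation
(infinite sites; synonymous mutations, one third of the total, are
implemented as a thinning of the rate, which is equivalent under infinite
sites).  Fixed and lost sites are dropped; the output is the set of
present-day population frequencies, all strictly inside (0, 1).

Two numerical choices matter:

* **Equilibrium initialisation.**  The ancestral epoch starts from the
  analytic drift–mutation equilibrium of the infinite-sites model — site
  counts at derived count `i` drawn Poisson with mean `theta/i`,
  `theta = 4·N1·u` (the Poisson-random-field stationary spectrum) — and
  is then relaxed for `N1` further Wright–Fisher generations.  Because
  the initial state is already stationary, a long burn-in is redundant;
  the relaxation only lets the finite-N binomial dynamics smooth any
  diffusion-approximation mismatch.  The oracle tests (Watterson's
  segregating-site expectation; the `theta/i` sample spectrum) check this
  directly.
* **Population rescaling.**  A factor `lambda` (`scale`, default 10 in
  the experiment configuration) divides all sizes and `T` and multiplies
  `mu_nt` and `rho`, preserving `theta = 4·N·mu` and `rho·T`.  This makes
  thousand-replicate studies run in minutes; a test checks that the
  sample site-frequency spectrum is statistically indistinguishable
  between `lambda = 1` and `lambda = 10`.  The one real difference is the
  granularity of the rarest frequencies (1/(2·N_present/lambda)); at the
  pool sizes used it is not detectable in the sampled data.

The per-nucleotide mutation rate defaults to `mu_nt = 1.8e-8` per
generation, the standard human point estimate; it is configuration-exposed
because the number of segregating sites per gene scales directly with it.
Estimating the demographic parameters from data, and natural selection,
are out of scope; the simulation is neutral.

## Cohort and phenotype model

Genotypes are drawn per site and individual as Binomial(2, q) —
Hardy–Weinberg equilibrium with **no linkage disequilibrium** between
sites.  This is a documented simplification: in real genes rare alleles
co-occur on related haplotype backgrounds, which the independent-site
model ignores.

A fixed count `round(f·L_n)` of the rare (MAF < 1%) variants is flagged
causative, chosen uniformly (fixed-count rather than per-variant Bernoulli
selection removes between-replicate variance in the architecture;
`f = 0.2` by default).  All common variants are treated as causative,
acting individually.  Phenotypes follow

    y_j = mu + beta·c_j + sum_k beta_k·g_jk + e_j,
    c_j = sum_l I_l·g_jl  (rare causative sites),
    e_j ~ Normal(0, error_variance).

`beta` is calibrated against the *empirical* pool variance of `c` so that
the rare score explains `h2·rare_share` of the phenotypic variance
(`beta = sqrt(h2_r·sigma_e² / ((1 − h2_r)·var(c))`); the common share
`h2·(1 − rare_share)` is split equally on the variance scale across the
`m` common variants, with
`beta_k = sqrt((h2·(1−rare_share)/m)·sigma_e²/((1−h2)·2q_k(1−q_k)))`.
When a panel has no common variant the common share is reassigned to the
rare score, so `h2` is always realised.  Only variance ratios are
identified, so `mu = 0` and `error_variance = 1` by default.  Parameter
recovery is tested: regressing `y` on the genetic predictors on large
pools returns R² within Monte-Carlo error of `h2`.

Extreme sampling takes the `n_u` lowest phenotypes as controls and the
`n_c` highest as cases (defaults 1,000 + 1,000 from a pool of 50,000),
ties broken by stable index order.

## Functional-prediction model

Predictor output is simulated per variant: the binary call
`O ~ Bernoulli(rho1)` for causative and `Bernoulli(rho2)` for neutral
variants; given the call, the continuous measure is uniform on the
matching side of the declaration threshold `a`: `p | O=1 ~ U[a, 1)`,
`p | O=0 ~ U[0, a)`.  Defaults `rho1 = 0.8`, `rho2 = 0.15`, `a = 0.9`
are midpoints of published predictor characteristics.  **Terminology
warning:** in this literature "specificity" is the false-positive rate
`P(O=1 | neutral)`, the inverse of the conventional definition; the code
keeps the field's usage and says so in the docstrings.  Measures are
redrawn fresh on every replicate.

The benefit of weighting is summarised by the effective causative
proportion `f' = f·rho1/(f·rho1 + (1−f)·rho2)`, which exceeds `f` exactly
when `rho1 > rho2`.

## Association tests

The three burden tests (ST, FWCST, FWBST) fit
`logit(q_j) = alpha + gamma·s_j + delta'x_j` by maximum likelihood
(statsmodels), with the common-variant genotypes `x_j` retained under
both hypotheses, and report the 1-df **likelihood-ratio** p-value for
`gamma = 0`.  The LRT was chosen over the Wald statistic because power is
evaluated at `alpha = 1e-6`, where Wald is unstable near separation.  A
constant score returns p = 1 with a `degenerate predictor` diagnostic.
If the ML fit fails to converge, separates, or returns extreme
coefficients, the test falls back to a Firth (Jeffreys-prior) penalised
fit written in-package — Newton iterations on the modified score with
step halving — and the penalised likelihood-ratio is referred to
chi-square(1), flagged `firth fallback` in the diagnostics.

CMC collapses the rare variants to a carrier indicator.  Without common
variants the 2×2 carrier-by-status table gets a two-sided Fisher exact
test (a chi-square variant is available behind `method="chisq"`); with
`m` common variants the `(m+1)`-vector is compared between groups by the
two-sample Hotelling T² with the exact F transformation.  Constant or
collinear columns are pruned greedily (rank-revealing) with a diagnostic.

GWWS weights each rare variant by `w_l = sqrt(n·q_l(1−q_l))` with the
frequency `q_l = (m_l^U + 1)/(2·n_U + 2)` anchored in the control group,
ranks the weighted scores, and sums the case ranks.  Weights and ranks
are recomputed inside each of the `k` label permutations (default
`k = 1,000`), vectorised across permutations; the p-value is the
two-sided normal tail of the z-score of the observed statistic against
the permutation mean and SD.  The z construction is what makes the test
usable at `alpha = 1e-6`, where raw counting over 1,000 permutations
cannot resolve p; a test checks the z-based p against the raw permutation
p in the moderate-p band where both are defined.  Two-sided throughout,
matching the symmetry of two-tail sampling.

In simulated data the rare/common partition uses the population frequency
(the truth is known); in applied variant tables it uses the sample minor
allele frequency at the same 1% threshold.  Missing genotypes in applied
matrices are not modelled; count-based tables are expanded with each
reported allele on a distinct heterozygous carrier (the plausible
configuration for rare variants), assigned reproducibly under the seed.

## Evaluation engine

Each replicate re-runs the entire chain — frequencies, panel, causative
flags, pool, phenotypes, extreme sample, prediction measures, tests —
with an independent random stream derived from the master seed via
`SeedSequence(master, spawn_key=(replicate, attempt))`, so results are
reproducible and independent of execution order.  Replicates with no
observable rare variant (or no causative allele in the pool when
`h2 > 0`) are redrawn and counted in the diagnostics.  Type-I error is
estimated at `h2 = 0`; power at `alpha = 1e-6`.

One exact optimisation: genotypes at phenotype-relevant sites (rare
causative plus common) are drawn for the whole pool to compute phenotypes
and select the extremes; genotypes at the remaining neutral sites are
drawn only for the sequenced individuals.  Under independent sites, HWE
and exchangeable individuals this is distribution-identical to genotyping
the full pool (a test compares the two chains' tail enrichment).

### Problem sizes

The package's study defaults are chosen for desk-scale reproduction:
population rescaling `lambda = 10`, 300 replicates per power design
point, 1,000–2,000 replicates for calibration checks.  At these sizes a
full power point takes under a minute on one CPU and Monte-Carlo SEs are
±2–3 percentage points; full-scale studies at 10,000 replicates run with
the same code by raising `replicates`.

## Known limitations

* No linkage disequilibrium between sites, no haplotype structure, no
  recombination model; real rare-variant co-carriage patterns differ.
* Neutral demography only; purifying selection, which shapes real
  nonsynonymous spectra, is not modelled, so simulated genes carry more
  moderately-rare variation than selection would allow.
* Prediction errors are independent of allele frequency and of each
  other; real predictor errors correlate with conservation and frequency.
* The applied-data path reconstructs genotypes from carrier counts; with
  counts approaching group sizes the distinct-heterozygote assumption
  becomes implausible (flagged).
* Passing the simulation suite shows the tests behave as designed under
  this generative model, not that the same power rankings hold for any
  real gene.

## Where design was genuinely open

* The continuous-score scale for applied data: PSIC scores are unbounded,
  simulation weights live in [0, 1].  Convention: nonsense variants are
  anchored at the maximum observed score (they are treated as functional
  with the highest weight), then the grouped set is min–max rescaled to
  [0, 1].  The test decision is not affine-invariant, so the convention
  is fixed and documented rather than configurable.
* How many common variants are causative, and how their 10% heritability
  share is divided, is not fixed by the model description: all of them,
  equal variance shares — deterministic and degenerate-safe.
* Power tables in this literature often report one "sequenced sample
  size" number, leaving per-group versus total ambiguous; the experiment
  configuration here always states `n_cases` and `n_controls` explicitly.
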