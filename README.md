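# rareweight

Rare-variant association tests that weight each variant by the output of a
functional-prediction algorithm (PolyPhen/SIFT-style), together with the
simulation machinery needed to study their type-I error and power in
extreme-phenotype sequencing designs.

## The problem

Gene-based sequencing studies group the rare nonsynonymous variants of a
gene into one per-individual burden score, because individually each variant
is too rare to test.  Most rare nonsynonymous variants are neutral, so the
unweighted burden drowns the causative signal in background variation.
Functional-prediction algorithms emit, per amino-acid substitution, a
qualitative call (damaging or benign) and a quantitative score; using these
as weights raises the *effective proportion of causative variants* in the
group,

    f' = f·ρ₁ / (f·ρ₁ + (1−f)·ρ₂),

where f is the true causative proportion, ρ₁ the predictor's sensitivity
(P(called functional | causative)) and ρ₂ its false-positive rate
(P(called functional | neutral) — called "specificity" in this literature;
note the inversion of the usual meaning).  Weighting helps exactly when
ρ₁ > ρ₂.

## The tests

For individual *j* with genotypes g_jl ∈ {0,1,2} at the Lₙ rare
nonsynonymous sites, with per-site continuous weights p_l and binary calls
o_l:

| test  | score s_j            | inference |
|-------|----------------------|-----------|
| ST    | Σ_l g_jl             | logistic LRT (1 df), common variants as covariates |
| FWCST | Σ_l p_l·g_jl         | same |
| FWBST | Σ_l o_l·g_jl         | same |
| CMC   | carrier indicator    | Fisher exact, or Hotelling T² jointly with common variants |
| GWWS  | Σ_l g_jl/w_l         | rank sum, permutation-calibrated z (weights w_l = √(n·q_l(1−q_l)), q_l anchored in controls) |

The case/control sample comes from the two tails of a quantitatively
phenotyped pool: phenotypes follow y_j = μ + β·c_j + Σ_k β_k g_jk + e_j with
causative score c_j = Σ_l I_l·g_jl, and β calibrated so the gene explains a
locus heritability h² (default 0.5%, 90% of it on rare variants).  Site
frequencies come from a forward Wright–Fisher simulation of the European
bottleneck-plus-growth demography (N₁ = 20,000 → N_b = 14,000, then
exponential growth at ρ = 0.001 for T = 3,300 generations, i.e. a
present-day effective size ≈ 380,000 and a bottleneck ~66 kya).

## Worked example

```python
import numpy as np
from rareweight import (
    DemographicParams, GeneModel, simulate_site_frequencies,
    VariantPanel, assign_causative, draw_genotypes, simulate_phenotypes,
    PhenotypeModel, CohortPool, SamplingDesign, extreme_sample,
    PredictionProfile, simulate_measures, RareVariantAssociation,
)

rng = np.random.default_rng(42)
sfs = simulate_site_frequencies(DemographicParams(), GeneModel(),
                                rng=rng, scale=10)
panel = assign_causative(VariantPanel.from_frequencies(sfs.freqs), 0.2, rng=rng)
g = draw_genotypes(panel.freqs, 50_000, rng=rng)
y = simulate_phenotypes(g, panel, PhenotypeModel(h2=0.005), rng=rng)
sample = extreme_sample(CohortPool(g, y, panel),
                        SamplingDesign(50_000, 1_000, 1_000))
simulate_measures(sample.panel, PredictionProfile(), rng=rng)

results = RareVariantAssociation.from_sample(sample).fit(k=1000, seed=1)
print(results.summary())
```

prints (seed 42):

```
Rare-variant association tests
  individuals: 2000 (1000 cases / 1000 controls)
  rare sites: 107, common sites: 7
 test  statistic   p_value  df_or_k    diagnostics
FWCST       13.4 0.0002518        1
FWBST      20.36 6.402e-06        1
   ST      4.314    0.0378        1
 GWWS       2.32   0.02032     1000
  CMC      27.61 0.0006109        8 hotelling path
```

The gene carries a real signal (h² = 0.5%, a fifth of its rare variants
causative): both functional-weighted tests see it far more clearly than the
unweighted burden (FWBST p ≈ 6e-6 vs ST p ≈ 0.04), because the weights
concentrate the score on the causative subset.

The same interface runs on published-style variant tables with carrier
counts and PolyPhen annotations:

```sh
rareweight fixture --profile dallas --seed 1 --out dallas.tsv
rareweight analyze --table dallas.tsv --k 1000 --seed 2 --out results.tsv
```

Monte-Carlo power and type-I-error studies run through
`rareweight evaluate` (or `rareweight.evaluation.sweep`), e.g.

```sh
rareweight evaluate --sweep h2 --grid 0,0.005,0.01,0.02 --reps 300 \
    --seed 7 --out power.tsv
```

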