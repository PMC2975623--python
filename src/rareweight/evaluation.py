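"""Monte-Carlo engine for type-I-error and power studies.

Each replicate re-runs the whole chain — site-frequency simulation,
genotype pool, causative assignment, phenotypes, extreme sampling,
prediction measures, association tests — with an independent random
stream derived from the master seed, so sweeps are reproducible and
order-independent.  Type-I error is estimated by setting the locus
heritability to zero; power is the proportion of replicates rejecting at
the chosen significance level (1e-6 by default, the genome-wide scale
used for the power studies).

For speed, genotypes at phenotype-relevant sites (causative rare plus
common variants) are drawn for the whole pool to compute phenotypes and
pick the extremes, and genotypes at the remaining neutral sites are drawn
only for the sequenced individuals.  Under the model's independence
assumptions (HWE, no linkage, exchangeable individuals) this is exactly
equivalent to genotyping the full pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association import TEST_ORDER, run_all_tests
from .cohort import (
    CaseControlSample,
    PhenotypeModel,
    SamplingDesign,
    VariantPanel,
    assign_causative,
    calibrate_beta,
    causative_score,
    common_variant_effects,
    draw_genotypes,
    extreme_sample,
)
from .demography import DemographicParams, GeneModel, simulate_site_frequencies
from .prediction import PredictionProfile, simulate_measures

__all__ = [
    "ExperimentConfig",
    "EvaluationResult",
    "simulate_case_control",
    "run_replicate",
    "estimate_rejection_rate",
    "estimate_rejection_rates",
    "sweep",
]

logger = logging.getLogger(__name__)

#: Sweepable configuration variables.
SWEEP_VARIABLES = (
    "f", "sensitivity", "specificity", "gene_length", "h2",
    "pool_size", "sequenced_size",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete configuration of one simulation experiment.

    Defaults are the baseline study conditions: 1,500-nt gene under the
    bottleneck-growth demography, pool of 50,000 phenotyped individuals,
    1,000 + 1,000 extremes sequenced, locus heritability 0.5% with 90% on
    rare variants, causative proportion f = 0.2, predictor sensitivity 0.8
    and false-positive rate 0.15, significance level 1e-6, population
    rescaling lambda = 10.
    """

    demography: DemographicParams = field(default_factory=DemographicParams)
    gene: GeneModel = field(default_factory=GeneModel)
    phenotype: PhenotypeModel = field(default_factory=PhenotypeModel)
    design: SamplingDesign = field(default_factory=SamplingDesign)
    predictor: PredictionProfile = field(default_factory=PredictionProfile)
    f_causative: float = 0.2
    scale: float = 10.0
    alpha: float = 1e-6
    replicates: int = 300
    k_permutations: int = 1000
    max_redraws: int = 100

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")


@dataclass
class EvaluationResult:
    """Rejection proportion for one test under one configuration."""

    test: str
    rate: float
    se: float
    replicates: int
    alpha: float
    n_degenerate: int = 0
    config: ExperimentConfig | None = None


def _replicate_rng(master_seed: int, index: int, attempt: int) -> np.random.Generator:
    """Independent, order-invariant stream for (replicate, redraw attempt)."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(index), int(attempt)))
    return np.random.default_rng(ss)


def _attempt_sample(config: ExperimentConfig, rng: np.random.Generator):
    """One attempt at the simulation chain; None if degenerate."""
    sfs = simulate_site_frequencies(
        config.demography, config.gene, scale=config.scale, rng=rng
    )
    if len(sfs) == 0:
        return None
    panel = VariantPanel.from_frequencies(sfs.freqs)
    if panel.n_rare == 0:
        return None
    assign_causative(panel, config.f_causative, rng=rng)

    model = config.phenotype
    design = config.design
    n_seq = design.n_controls + design.n_cases

    # phenotype-relevant sites: rare causative + common
    pheno_sites = np.flatnonzero((panel.causative & panel.rare) | ~panel.rare)
    g_pheno = draw_genotypes(panel.freqs[pheno_sites], design.pool_size, rng=rng)

    c = g_pheno[:, panel.rare[pheno_sites]].sum(axis=1).astype(float)
    h2_rare = model.h2 * model.rare_share
    if panel.n_common == 0:
        h2_rare = model.h2
    y = model.mu + rng.normal(0.0, math.sqrt(model.error_variance),
                              size=design.pool_size)
    if h2_rare > 0:
        var_c = float(c.var())
        if var_c == 0:
            return None  # no causative copies in the pool: cannot place h2
        y = y + calibrate_beta(h2_rare, var_c, model.error_variance) * c
    beta_k = common_variant_effects(panel, model)
    if beta_k.size:
        y = y + g_pheno[:, ~panel.rare[pheno_sites]] @ beta_k

    order = np.argsort(y, kind="stable")
    idx = np.concatenate([order[: design.n_controls],
                          order[design.pool_size - design.n_cases:]])
    status = np.concatenate([np.zeros(design.n_controls, dtype=int),
                             np.ones(design.n_cases, dtype=int)])

    genotypes = np.empty((n_seq, panel.n_sites), dtype=np.int8)
    genotypes[:, pheno_sites] = g_pheno[idx]
    other = np.setdiff1d(np.arange(panel.n_sites), pheno_sites)
    if other.size:
        genotypes[:, other] = draw_genotypes(panel.freqs[other], n_seq, rng=rng)

    # drop sites never observed in the sequenced sample
    seen = genotypes.sum(axis=0) > 0
    if not seen.any() or not (panel.rare & seen).any():
        return None
    panel = VariantPanel(
        freqs=panel.freqs[seen], causative=panel.causative[seen]
    )
    genotypes = genotypes[:, seen]

    simulate_measures(panel, config.predictor, rng=rng)
    return CaseControlSample(genotypes=genotypes, status=status, panel=panel)


def run_replicate(
    config: ExperimentConfig,
    replicate_seed: int,
    *,
    index: int = 0,
    tests=TEST_ORDER,
) -> tuple[dict, int]:
    """Execute one full-chain replicate.

    Returns ``(pvalues, n_degenerate)`` where ``pvalues`` maps test name to
    p-value and ``n_degenerate`` counts redrawn degenerate attempts
    (replicates with no observable rare variant or no causative copy).
    """
    for attempt in range(config.max_redraws):
        rng = _replicate_rng(replicate_seed, index, attempt)
        sample = _attempt_sample(config, rng)
        if sample is not None:
            results = run_all_tests(
                sample, k=config.k_permutations, tests=tests, rng=rng
            )
            return {r.test: r.p_value for r in results}, attempt
    raise RuntimeError(
        f"replicate {index}: {config.max_redraws} consecutive degenerate draws"
    )


def estimate_rejection_rates(
    config: ExperimentConfig,
    seed: int,
    *,
    reps: int | None = None,
    alpha: float | None = None,
    tests=TEST_ORDER,
) -> dict[str, EvaluationResult]:
    """Rejection proportion of each test over independent replicates."""
    reps = config.replicates if reps is None else reps
    alpha = config.alpha if alpha is None else alpha
    tests = tuple(t for t in TEST_ORDER if t in tests)
    hits = {t: 0 for t in tests}
    valid = {t: 0 for t in tests}
    n_degenerate = 0
    for i in range(reps):
        pvals, redraws = run_replicate(config, seed, index=i, tests=tests)
        n_degenerate += redraws
        for t in tests:
            p = pvals.get(t, np.nan)
            if np.isnan(p):
                continue
            valid[t] += 1
            if p <= alpha:
                hits[t] += 1
        if (i + 1) % 100 == 0:
            logger.debug("replicate %d/%d done", i + 1, reps)
    out = {}
    for t in tests:
        n = max(valid[t], 1)
        rate = hits[t] / n
        out[t] = EvaluationResult(
            test=t, rate=rate, se=math.sqrt(rate * (1 - rate) / n),
            replicates=valid[t], alpha=alpha, n_degenerate=n_degenerate,
            config=config,
        )
    return out


def estimate_rejection_rate(
    config: ExperimentConfig,
    test: str,
    reps: int,
    alpha: float,
    seed: int = 0,
) -> EvaluationResult:
    """Single-test convenience wrapper around :func:`estimate_rejection_rates`."""
    return estimate_rejection_rates(
        config, seed, reps=reps, alpha=alpha, tests=(test,)
    )[test]


def _apply_sweep_value(config: ExperimentConfig, variable: str, value) -> ExperimentConfig:
    if variable == "f":
        return replace(config, f_causative=float(value))
    if variable == "sensitivity":
        return replace(config, predictor=replace(config.predictor, sensitivity=float(value)))
    if variable == "specificity":
        return replace(config, predictor=replace(config.predictor, specificity=float(value)))
    if variable == "gene_length":
        return replace(config, gene=replace(config.gene, L=float(value)))
    if variable == "h2":
        return replace(config, phenotype=replace(config.phenotype, h2=float(value)))
    if variable == "pool_size":
        return replace(config, design=replace(config.design, pool_size=int(value)))
    if variable == "sequenced_size":
        half = int(value) // 2
        return replace(config, design=replace(config.design,
                                              n_cases=half, n_controls=half))
    raise ValueError(
        f"unknown sweep variable {variable!r}; choose from {SWEEP_VARIABLES}"
    )


def sweep(
    config: ExperimentConfig,
    variable: str,
    grid,
    reps: int,
    seed: int = 0,
    *,
    tests=TEST_ORDER,
) -> pd.DataFrame:
    """Rejection rates along a grid of one influential factor.

    All other parameters stay at their configured baseline.  Returns a
    tidy frame with columns (variable, value, test, rate, se, reps,
    degenerate).
    """
    rows = []
    for j, value in enumerate(grid):
        cfg = _apply_sweep_value(config, variable, value)
        # distinct, order-invariant seed per grid point
        point_seed = int(np.random.SeedSequence(
            entropy=int(seed), spawn_key=(10_000 + j,)).generate_state(1)[0] % (2**31))
        res = estimate_rejection_rates(cfg, point_seed, reps=reps, tests=tests)
        for t, r in res.items():
            rows.append({
                "variable": variable, "value": value, "test": t,
                "rate": r.rate, "se": r.se, "reps": r.replicates,
                "degenerate": r.n_degenerate,
            })
        logger.info("sweep %s=%s done", variable, value)
    return pd.DataFrame(rows)
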