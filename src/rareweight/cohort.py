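"""Quantitatively phenotyped cohort: genotypes, phenotypes, extreme sampling.

A pool of individuals is genotyped at the simulated sites under
Hardy-Weinberg equilibrium with no linkage disequilibrium, a fraction
``f`` of the rare nonsynonymous variants is flagged causative, and the
quantitative phenotype follows the additive linear model

    y_j = mu + beta * c_j + sum_k beta_k * g_jk + e_j,

where ``c_j = sum_l I_l * g_jl`` is the causative score over the rare
nonsynonymous variants, the second sum runs over common causative
variants acting individually, and ``e_j ~ Normal(0, error_variance)``.
``beta`` is calibrated so the rare score explains its share of the locus
heritability h^2.  The case/control sample is drawn from the two tails of
the phenotype distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RARE_MAF_THRESHOLD",
    "VariantPanel",
    "PhenotypeModel",
    "CohortPool",
    "SamplingDesign",
    "CaseControlSample",
    "draw_genotypes",
    "assign_causative",
    "causative_score",
    "calibrate_beta",
    "common_variant_effects",
    "simulate_phenotypes",
    "extreme_sample",
]

#: Minor-allele-frequency threshold separating rare from common variants.
RARE_MAF_THRESHOLD = 0.01


@dataclass
class VariantPanel:
    """Per-site description of the variants in one gene.

    Attributes
    ----------
    freqs : ndarray
        Population derived-allele frequencies, strictly in (0, 1).
    rare : ndarray of bool
        True where the minor-allele frequency is below 1%.
    causative : ndarray of bool
        Indicator I_l of causative variants.
    functional_binary : ndarray of int, optional
        Predicted-functional indicator O_l in {0, 1}.
    functional_score : ndarray of float, optional
        Continuous functional measure p_l.
    """

    freqs: np.ndarray
    rare: np.ndarray = None
    causative: np.ndarray = None
    functional_binary: np.ndarray | None = None
    functional_score: np.ndarray | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.size and not ((self.freqs > 0) & (self.freqs < 1)).all():
            raise ValueError("panel frequencies must lie strictly in (0, 1)")
        maf = np.minimum(self.freqs, 1.0 - self.freqs)
        if self.rare is None:
            self.rare = maf < RARE_MAF_THRESHOLD
        else:
            self.rare = np.asarray(self.rare, dtype=bool)
            if not np.array_equal(self.rare, maf < RARE_MAF_THRESHOLD):
                raise ValueError("rarity classes inconsistent with frequencies")
        if self.causative is None:
            self.causative = np.zeros(self.freqs.size, dtype=bool)
        else:
            self.causative = np.asarray(self.causative, dtype=bool)

    @property
    def n_sites(self) -> int:
        return int(self.freqs.size)

    @property
    def n_rare(self) -> int:
        """L_n, the number of rare nonsynonymous variants."""
        return int(self.rare.sum())

    @property
    def n_common(self) -> int:
        """m, the number of common variants."""
        return int((~self.rare).sum())

    @classmethod
    def from_frequencies(cls, freqs) -> "VariantPanel":
        return cls(freqs=np.asarray(freqs, dtype=float))


@dataclass(frozen=True)
class PhenotypeModel:
    """Linear phenotype model parameters.

    ``h2`` is the locus heritability: the fraction of the total phenotypic
    variance attributable to the gene's causative variants.  ``rare_share``
    is the fraction of h^2 carried by the rare-variant causative score
    (default 0.9, leaving 10% to common variants).  Only the ratio of
    genetic to error variance is identified, so ``mu`` defaults to 0 and
    ``error_variance`` to 1.
    """

    mu: float = 0.0
    h2: float = 0.005
    rare_share: float = 0.9
    error_variance: float = 1.0

    def __post_init__(self):
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must be in [0, 1)")
        if not 0 <= self.rare_share <= 1:
            raise ValueError("rare_share must be in [0, 1]")
        if self.error_variance <= 0:
            raise ValueError("error_variance must be positive")


@dataclass
class CohortPool:
    """Genotypes g_jl and phenotypes y_j of the phenotyped pool."""

    genotypes: np.ndarray
    phenotypes: np.ndarray
    panel: VariantPanel

    def __post_init__(self):
        if self.genotypes.shape[0] != self.phenotypes.shape[0]:
            raise ValueError("genotype rows must match phenotype length")

    @property
    def size(self) -> int:
        return int(self.genotypes.shape[0])


@dataclass(frozen=True)
class SamplingDesign:
    """Pool size and the numbers of extreme individuals sequenced."""

    pool_size: int = 50_000
    n_controls: int = 1_000
    n_cases: int = 1_000

    def __post_init__(self):
        if self.pool_size <= 0:
            raise ValueError("pool_size must be positive")
        if self.n_controls < 0 or self.n_cases < 0:
            raise ValueError("sample sizes must be non-negative")
        if self.n_controls + self.n_cases > self.pool_size:
            raise ValueError("n_controls + n_cases exceeds the pool size")


@dataclass
class CaseControlSample:
    """Extreme-phenotype sample: genotypes plus 0/1 status (1 = case)."""

    genotypes: np.ndarray
    status: np.ndarray
    panel: VariantPanel

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=int)
        if self.genotypes.shape[0] != self.status.shape[0]:
            raise ValueError("genotype rows must match status length")

    @property
    def n_cases(self) -> int:
        return int((self.status == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())


def draw_genotypes(
    freqs, pool_size: int, seed=None, *, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw a (pool_size x sites) genotype matrix under HWE.

    Each genotype is Binomial(2, freq_l), independent across individuals
    and sites (no linkage disequilibrium).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if pool_size <= 0:
        raise ValueError("pool_size must be positive")
    freqs = np.asarray(getattr(freqs, "freqs", freqs), dtype=float)
    if freqs.size and ((freqs < 0) | (freqs >= 1)).any():
        raise ValueError("frequencies must lie in [0, 1)")
    return rng.binomial(2, freqs, size=(pool_size, freqs.size)).astype(np.int8)


def assign_causative(
    panel: VariantPanel, f: float, seed=None, *,
    rng: np.random.Generator | None = None,
) -> VariantPanel:
    """Flag causative variants in place and return the panel.

    Exactly ``round(f * L_n)`` rare variants are chosen uniformly at random
    (fixed-count selection, which removes between-replicate variance in the
    simulated architecture).  Every common variant in the panel is flagged
    causative; its 10% heritability share is handled by
    :func:`common_variant_effects`.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    causative = np.zeros(panel.n_sites, dtype=bool)
    rare_idx = np.flatnonzero(panel.rare)
    n_flag = int(round(f * rare_idx.size))
    if n_flag:
        causative[rng.choice(rare_idx, size=n_flag, replace=False)] = True
    causative[~panel.rare] = True
    panel.causative = causative
    return panel


def causative_score(genotypes: np.ndarray, panel: VariantPanel) -> np.ndarray:
    """c_j = sum over rare causative sites of I_l * g_jl, per individual."""
    mask = panel.causative & panel.rare
    if genotypes.shape[1] != panel.n_sites:
        raise ValueError("genotype columns must match panel sites")
    return genotypes[:, mask].sum(axis=1).astype(np.int64)


def calibrate_beta(h2_component: float, var_c: float, error_variance: float) -> float:
    """Effect size placing a variance fraction ``h2_component`` on a score.

    Solves beta^2 * var_c / (beta^2 * var_c + error_variance) =
    h2_component, i.e. beta = sqrt(h2_component * error_variance /
    ((1 - h2_component) * var_c)).
    """
    if not 0 <= h2_component < 1:
        raise ValueError("h2_component must be in [0, 1)")
    if h2_component == 0:
        return 0.0
    if var_c <= 0:
        raise ValueError("cannot place heritability on a constant score")
    return math.sqrt(
        h2_component * error_variance / ((1.0 - h2_component) * var_c)
    )


def common_variant_effects(panel: VariantPanel, model: PhenotypeModel) -> np.ndarray:
    """Per-variant effects beta_k for the common causative variants.

    The common share ``h2 * (1 - rare_share)`` is split equally among the
    ``m`` common variants on the variance scale:

        beta_k = sqrt((h2*(1-rare_share)/m) * error_variance
                      / ((1-h2) * 2*q_k*(1-q_k))).

    Returns an empty array when m = 0 (the share is then reassigned to the
    rare score by :func:`simulate_phenotypes`).
    """
    q = panel.freqs[~panel.rare]
    m = q.size
    if m == 0 or model.h2 == 0 or model.rare_share == 1.0:
        return np.zeros(m)
    share = model.h2 * (1.0 - model.rare_share) / m
    return np.sqrt(
        share * model.error_variance / ((1.0 - model.h2) * 2.0 * q * (1.0 - q))
    )


def simulate_phenotypes(
    genotypes: np.ndarray,
    panel: VariantPanel,
    model: PhenotypeModel,
    seed=None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate phenotypes under the additive linear model.

    The rare-score effect ``beta`` is calibrated against the empirical
    variance of the causative score in this pool so that the score explains
    ``h2 * rare_share`` of the phenotypic variance; if the panel has no
    common variant the full ``h2`` is placed on the rare score.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = genotypes.shape[0]
    y = model.mu + rng.normal(0.0, math.sqrt(model.error_variance), size=n)

    c = causative_score(genotypes, panel)
    h2_rare = model.h2 * model.rare_share
    if panel.n_common == 0:
        h2_rare = model.h2
    if h2_rare > 0:
        var_c = float(c.var())
        beta = calibrate_beta(h2_rare, var_c, model.error_variance)
        y = y + beta * c

    beta_k = common_variant_effects(panel, model)
    if beta_k.size:
        x = genotypes[:, ~panel.rare]
        y = y + x @ beta_k
    return y


def extreme_sample(pool: CohortPool, design: SamplingDesign) -> CaseControlSample:
    """Sequence the two tails of the phenotype distribution.

    The ``n_controls`` lowest phenotypes become controls (status 0) and the
    ``n_cases`` highest become cases (status 1).  Ties are broken by stable
    order of individual index.
    """
    if design.n_controls + design.n_cases > pool.size:
        raise ValueError("design asks for more individuals than the pool holds")
    order = np.argsort(pool.phenotypes, kind="stable")
    low = order[: design.n_controls]
    high = order[pool.size - design.n_cases:]
    idx = np.concatenate([low, high])
    status = np.concatenate(
        [np.zeros(design.n_controls, dtype=int), np.ones(design.n_cases, dtype=int)]
    )
    return CaseControlSample(
        genotypes=pool.genotypes[idx], status=status, panel=pool.panel
    )
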