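"""Rare-variant association tests on an extreme-phenotype case/control sample.

Five tests share the rare/common partition of a variant panel:

* **ST** — sum test: burden score s_j = sum_l g_jl over rare variants,
  tested by a logistic likelihood-ratio test with common-variant
  covariates.
* **FWCST** — functional-weighted continuous sum test: s_j = sum_l p_l g_jl
  with the predictor's continuous scores as weights, same logistic test.
* **FWBST** — functional-weighted binary sum test: s_j = sum_l o_l g_jl
  with the predictor's 0/1 calls as weights; identical to ST when every
  o_l = 1.
* **CMC** — combined multivariate and collapsing: rare variants collapse
  to a carrier indicator, tested by Fisher's exact test (no common
  variants) or jointly with the common variants by Hotelling's T^2.
* **GWWS** — group-wise weighted sum: genotypes weighted inversely to a
  control-anchored frequency standard deviation, rank-sum statistic with
  permutation-calibrated significance.

The statsmodels-style entry point is :class:`RareVariantAssociation`,
whose ``fit`` returns an :class:`AssociationResults` with per-test
p-values and a ``summary`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CaseControlSample, VariantPanel

__all__ = [
    "TEST_ORDER",
    "EncodedScores",
    "TestResult",
    "encode_st",
    "encode_fwcst",
    "encode_fwbst",
    "logistic_burden_test",
    "cmc_test",
    "madsen_browning_weights",
    "gwws_test",
    "run_all_tests",
    "RareVariantAssociation",
    "AssociationResults",
]

#: Canonical ordering of the five tests in batch output.
TEST_ORDER = ("FWCST", "FWBST", "ST", "GWWS", "CMC")


@dataclass
class EncodedScores:
    """Per-individual burden scores s_j under one encoding scheme."""

    values: np.ndarray
    scheme: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values < 0).any():
            raise ValueError("burden scores must be non-negative")


@dataclass
class TestResult:
    """Outcome of one association test."""

    test: str
    p_value: float
    statistic: float = np.nan
    df_or_k: float | None = None
    diagnostics: tuple = ()

    def __post_init__(self):
        if not np.isnan(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def _rare_matrix(genotypes: np.ndarray) -> np.ndarray:
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise ValueError("genotypes must be a 2-D (individuals x sites) matrix")
    if g.shape[1] == 0:
        raise ValueError("no rare variants to group")
    return g


def encode_st(rare_genotypes: np.ndarray) -> EncodedScores:
    """Unweighted burden: s_j = sum_l g_jl over the rare variants."""
    g = _rare_matrix(rare_genotypes)
    return EncodedScores(g.sum(axis=1), "ST")


def encode_fwcst(rare_genotypes: np.ndarray, weights: np.ndarray) -> EncodedScores:
    """Continuous functional weighting: s_j = sum_l p_l * g_jl."""
    g = _rare_matrix(rare_genotypes)
    w = np.asarray(weights, dtype=float)
    if w.shape != (g.shape[1],):
        raise ValueError("one continuous weight is required per rare site")
    return EncodedScores(g @ w, "FWCST")


def encode_fwbst(rare_genotypes: np.ndarray, calls: np.ndarray) -> EncodedScores:
    """Binary functional weighting: s_j = sum_l o_l * g_jl, o_l in {0, 1}."""
    g = _rare_matrix(rare_genotypes)
    o = np.asarray(calls)
    if o.shape != (g.shape[1],):
        raise ValueError("one binary weight is required per rare site")
    if not np.isin(o, (0, 1)).all():
        raise ValueError("binary weights must be 0 or 1")
    return EncodedScores(g @ o.astype(float), "FWBST")


# ---------------------------------------------------------------------------
# logistic likelihood-ratio machinery

def _firth_loglik(X: np.ndarray, y: np.ndarray, max_iter: int = 100) -> float:
    """Penalised log-likelihood of a Firth (Jeffreys-prior) logistic fit.

    Newton iterations on the modified score U* = X'(y - p + h*(0.5 - p))
    with h the leverages of the weighted design; finite for separated data,
    which is why it backs the plain ML fit up.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info = info + 1e-8 * np.eye(k)
            cov = np.linalg.inv(info)
        # leverages of W^(1/2) X
        h = np.einsum("ij,jk,ik->i", X * w[:, None], cov, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = cov @ score
        # step halving for stability
        for _ in range(10):
            if np.max(np.abs(step)) <= 5.0:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
    w = p * (1.0 - p)
    sign, logdet = np.linalg.slogdet((X.T * w) @ X)
    return float(ll + 0.5 * logdet)


def _ml_loglik(X: np.ndarray, y: np.ndarray) -> float | None:
    """Maximum log-likelihood of a logistic fit, or None when unstable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, disp=0,
                                     warn_convergence=False)
        except Exception:
            return None
    if not res.mle_retvals.get("converged", False):
        return None
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 30:
        return None
    return float(res.llf)


def _drop_constant_columns(x: np.ndarray) -> tuple[np.ndarray, bool]:
    if x.size == 0:
        return x, False
    keep = x.std(axis=0) > 0
    return x[:, keep], bool((~keep).any())


def logistic_burden_test(
    scores: EncodedScores,
    status: np.ndarray,
    common_genotypes: np.ndarray | None = None,
) -> TestResult:
    """Likelihood-ratio test of the burden score in a logistic model.

    Fits logit(q_j) = alpha + gamma*s_j + delta'x_j by maximum likelihood,
    where x_j are the common-variant genotypes (retained under both
    hypotheses), and returns the 1-df likelihood-ratio p-value for
    H0: gamma = 0.  A constant score yields p = 1 with a
    ``degenerate predictor`` diagnostic; non-convergence or separation
    falls back to a Firth-penalised likelihood ratio, flagged
    ``firth fallback``.
    """
    s = np.asarray(scores.values, dtype=float)
    y = np.asarray(status, dtype=float)
    n = y.size
    if s.size != n:
        raise ValueError("scores and status lengths differ")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least two individuals per status group")

    diagnostics = []
    if s.std() == 0:
        return TestResult(scores.scheme, 1.0, 0.0, 1,
                          ("degenerate predictor",))

    if common_genotypes is None:
        x = np.empty((n, 0))
    else:
        x = np.asarray(common_genotypes, dtype=float).reshape(n, -1)
    x, dropped = _drop_constant_columns(x)
    if dropped:
        diagnostics.append("dropped constant covariate")

    X0 = np.column_stack([np.ones(n), x])
    X1 = np.column_stack([np.ones(n), s, x])

    ll0 = _ml_loglik(X0, y)
    ll1 = _ml_loglik(X1, y)
    if ll0 is None or ll1 is None:
        diagnostics.append("firth fallback")
        ll0 = _firth_loglik(X0, y)
        ll1 = _firth_loglik(X1, y)

    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, 1))
    return TestResult(scores.scheme, p, lr, 1, tuple(diagnostics))


# ---------------------------------------------------------------------------
# CMC

def _independent_columns(v: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent, non-constant column set."""
    keep: list[int] = []
    centered = v - v.mean(axis=0)
    for j in range(v.shape[1]):
        cand = centered[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    return np.array(keep, dtype=int)


def cmc_test(
    rare_genotypes: np.ndarray,
    status: np.ndarray,
    common_genotypes: np.ndarray | None = None,
    *,
    method: str = "fisher",
) -> TestResult:
    """Combined multivariate and collapsing test.

    Rare variants collapse to the carrier indicator z_j = 1 if any rare
    allele is carried.  Without common variants the 2x2 carrier-by-status
    table is tested by a two-sided Fisher exact test (``method="chisq"``
    switches to the chi-square test).  With ``m`` common variants the
    (m+1)-vector [z_j, x_j] is compared between groups by the two-sample
    Hotelling T^2, with the p-value from the exact F transformation.
    Collinear or constant columns are dropped with a diagnostic.
    """
    g = _rare_matrix(rare_genotypes)
    y = np.asarray(status, dtype=int)
    z = (g.sum(axis=1) > 0).astype(float)
    diagnostics: list[str] = []

    m = 0 if common_genotypes is None else np.asarray(common_genotypes).reshape(len(y), -1).shape[1]
    if m == 0:
        carriers_case = int(z[y == 1].sum())
        carriers_ctrl = int(z[y == 0].sum())
        n_case = int((y == 1).sum())
        n_ctrl = int((y == 0).sum())
        table = [[carriers_case, n_case - carriers_case],
                 [carriers_ctrl, n_ctrl - carriers_ctrl]]
        if method == "chisq":
            res = stats.chi2_contingency(table, correction=False)
            return TestResult("CMC", float(res.pvalue), float(res.statistic), 1,
                              ("chisq path",))
        stat, p = stats.fisher_exact(table, alternative="two-sided")
        return TestResult("CMC", float(p), float(stat), None, ("fisher path",))

    x = np.asarray(common_genotypes, dtype=float).reshape(len(y), -1)
    v = np.column_stack([z, x])
    keep = _independent_columns(v)
    if keep.size < v.shape[1]:
        diagnostics.append("dropped collinear columns")
    if keep.size == 0:
        return TestResult("CMC", 1.0, 0.0, None,
                          tuple(diagnostics) + ("degenerate predictor",))
    v = v[:, keep]

    v1, v2 = v[y == 1], v[y == 0]
    n1, n2, p_dim = len(v1), len(v2), v.shape[1]
    d = v1.mean(axis=0) - v2.mean(axis=0)
    s_pool = ((n1 - 1) * np.cov(v1, rowvar=False, ddof=1).reshape(p_dim, p_dim)
              + (n2 - 1) * np.cov(v2, rowvar=False, ddof=1).reshape(p_dim, p_dim)
              ) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(s_pool, d)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(s_pool, d, rcond=None)[0]
        diagnostics.append("singular pooled covariance")
    t2 = n1 * n2 / (n1 + n2) * float(d @ sol)
    df2 = n1 + n2 - p_dim - 1
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p_dim)
    p = float(stats.f.sf(f_stat, p_dim, df2))
    return TestResult("CMC", p, t2, p_dim, tuple(diagnostics) + ("hotelling path",))


# ---------------------------------------------------------------------------
# GWWS

def madsen_browning_weights(rare_genotypes: np.ndarray, case_mask: np.ndarray):
    """Control-anchored frequency estimates and weights, per rare variant.

    q_l = (m_l^U + 1) / (2 n_U + 2) with m_l^U the mutant-allele count
    among the n_U controls; w_l = sqrt(n_l * q_l * (1 - q_l)) with n_l the
    number of genotyped individuals.  ``case_mask`` may be a matrix with
    one labelling per column (used for the permutation recomputation).
    Returns ``(q, w)``.
    """
    g = np.asarray(rare_genotypes, dtype=float)
    m = np.asarray(case_mask, dtype=float)
    n = g.shape[0]
    n_ctrl = (1.0 - m).sum(axis=0) if m.ndim == 2 else float((1.0 - m).sum())
    m_u = g.T @ (1.0 - m)
    q = (m_u + 1.0) / (2.0 * n_ctrl + 2.0)
    w = np.sqrt(n * q * (1.0 - q))
    return q, w


def gwws_test(
    rare_genotypes: np.ndarray,
    status: np.ndarray,
    k: int = 1000,
    seed=None,
    *,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """Group-wise weighted sum test with permutation-calibrated rank sum.

    Each rare variant receives weight w_l = sqrt(n_l * q_l * (1 - q_l))
    where q_l = (m_l^U + 1) / (2 n_U + 2) anchors the frequency in the
    control group (m_l^U mutant alleles among n_U controls, n_l genotyped
    individuals).  Individual scores gamma_j = sum_l g_jl / w_l are ranked
    over the whole sample and the statistic is the sum of case ranks.  The
    weighting-ranking procedure is repeated on ``k`` label permutations
    (weights recomputed from each permuted control group); the p-value is
    the two-sided normal tail of the z-score of the observed statistic
    against the permutation mean and SD.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    g = _rare_matrix(rare_genotypes).astype(float)
    y = np.asarray(status, dtype=int)
    n, n_sites = g.shape
    if y.size != n:
        raise ValueError("status length must match genotype rows")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_case = int((y == 1).sum())

    # column 0 is the observed labelling, columns 1..k are permutations
    case_masks = np.empty((n, k + 1), dtype=float)
    case_masks[:, 0] = y == 1
    for i in range(1, k + 1):
        perm = rng.permutation(n)
        case_masks[:, i] = 0.0
        case_masks[perm[:n_case], i] = 1.0

    q, w = madsen_browning_weights(g, case_masks)     # (sites x k+1)
    gamma = g @ (1.0 / w)                             # (n x k+1)
    ranks = stats.rankdata(gamma, axis=0, method="average")
    x = (ranks * case_masks).sum(axis=0)

    mean = x[1:].mean()
    sd = x[1:].std(ddof=1)
    if sd == 0:
        return TestResult("GWWS", 1.0, float(x[0]), k, ("degenerate permutations",))
    z = (x[0] - mean) / sd
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult("GWWS", p, float(z), k)


# ---------------------------------------------------------------------------
# batch runner and model surface

def _partition(sample: CaseControlSample):
    panel = sample.panel
    rare = panel.rare
    g_rare = np.asarray(sample.genotypes)[:, rare]
    g_common = np.asarray(sample.genotypes)[:, ~rare]
    p_w = None if panel.functional_score is None else panel.functional_score[rare]
    o_w = None if panel.functional_binary is None else panel.functional_binary[rare]
    return g_rare, g_common, p_w, o_w


def run_all_tests(
    sample: CaseControlSample,
    k: int = 1000,
    seed=None,
    *,
    tests=TEST_ORDER,
    rng: np.random.Generator | None = None,
) -> list[TestResult]:
    """Run the requested tests on a sample, sharing the rare/common split.

    Results come back in the canonical order FWCST, FWBST, ST, GWWS, CMC
    (restricted to ``tests``).  A per-test failure is recorded as a result
    with a NaN p-value and an error diagnostic rather than aborting the
    batch.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    g_rare, g_common, p_w, o_w = _partition(sample)
    y = sample.status
    out: list[TestResult] = []
    for name in TEST_ORDER:
        if name not in tests:
            continue
        try:
            if name == "ST":
                out.append(logistic_burden_test(encode_st(g_rare), y, g_common))
            elif name == "FWCST":
                if p_w is None:
                    raise ValueError("panel has no continuous functional scores")
                out.append(logistic_burden_test(encode_fwcst(g_rare, p_w), y, g_common))
            elif name == "FWBST":
                if o_w is None:
                    raise ValueError("panel has no binary functional calls")
                out.append(logistic_burden_test(encode_fwbst(g_rare, o_w), y, g_common))
            elif name == "GWWS":
                out.append(gwws_test(g_rare, y, k=k, rng=rng))
            elif name == "CMC":
                common = g_common if g_common.shape[1] else None
                out.append(cmc_test(g_rare, y, common))
        except Exception as exc:  # keep the batch alive
            out.append(TestResult(name, np.nan, np.nan, None, (f"error: {exc}",)))
    return out


class RareVariantAssociation:
    """Rare-variant association model for one gene region.

    Statsmodels-flavoured surface: construct from data, call :meth:`fit`,
    inspect the returned :class:`AssociationResults`.

    Parameters
    ----------
    genotypes : ndarray (individuals x sites)
        Genotypes coded 0/1/2.
    status : ndarray
        1 for cases, 0 for controls.
    panel : VariantPanel
        Site frequencies, rare/common classes and (optionally) functional
        measures; required for the weighted tests.
    """

    def __init__(self, genotypes, status, panel: VariantPanel):
        self.sample = CaseControlSample(
            genotypes=np.asarray(genotypes), status=np.asarray(status), panel=panel
        )

    @classmethod
    def from_sample(cls, sample: CaseControlSample) -> "RareVariantAssociation":
        obj = cls.__new__(cls)
        obj.sample = sample
        return obj

    @classmethod
    def from_dataframe(
        cls, genotypes: pd.DataFrame, status, panel: VariantPanel
    ) -> "RareVariantAssociation":
        """Build from a (individuals x sites) genotype DataFrame."""
        return cls(genotypes.to_numpy(), np.asarray(status), panel)

    def fit(self, tests=TEST_ORDER, k: int = 1000, seed=None) -> "AssociationResults":
        """Run the association tests and return the results object."""
        results = run_all_tests(self.sample, k=k, seed=seed, tests=tests)
        return AssociationResults(self, results)


class AssociationResults:
    """Fitted results: per-test p-values, statistics and diagnostics."""

    def __init__(self, model: RareVariantAssociation, results: list[TestResult]):
        self.model = model
        self.results = results

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series({r.test: r.p_value for r in self.results}, name="p_value")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test": [r.test for r in self.results],
                "statistic": [r.statistic for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "df_or_k": [r.df_or_k for r in self.results],
                "diagnostics": ["; ".join(r.diagnostics) for r in self.results],
            }
        )

    def summary(self) -> str:
        """Plain-text summary table of the fitted tests."""
        sample = self.model.sample
        head = (
            "Rare-variant association tests\n"
            f"  individuals: {len(sample.status)} "
            f"({sample.n_cases} cases / {sample.n_controls} controls)\n"
            f"  rare sites: {int(sample.panel.rare.sum())}, "
            f"common sites: {int((~sample.panel.rare).sum())}\n"
        )
        body = self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4g}")
        return head + body
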