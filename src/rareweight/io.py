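"""Annotated variant tables, annotation-to-weight mapping, applied analysis.

Applied analyses start from a tab-separated variant table in the shape
published by pooled candidate-gene sequencing studies: per-variant carrier
counts in two extreme-phenotype groups plus a PolyPhen-style annotation (a
qualitative category and a PSIC-like quantitative score).  The mandatory
header is::

    variant_id  gene  cases_carriers  controls_carriers  n_cases
    n_controls  category  score

with ``category`` one of benign / possibly_damaging / probably_damaging /
nonsense and ``score`` a number (``.`` marks a missing score, allowed only
for nonsense variants, which PolyPhen cannot evaluate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import TestResult, run_all_tests
from .cohort import CaseControlSample, VariantPanel, RARE_MAF_THRESHOLD

__all__ = [
    "CATEGORIES",
    "VARIANT_TABLE_COLUMNS",
    "AnnotatedVariantTable",
    "read_variant_table",
    "write_variant_table",
    "annotation_to_weights",
    "binomial_damaging_enrichment",
    "table_to_sample",
    "analyze_real",
]

CATEGORIES = ("benign", "possibly_damaging", "probably_damaging", "nonsense")
VARIANT_TABLE_COLUMNS = (
    "variant_id", "gene", "cases_carriers", "controls_carriers",
    "n_cases", "n_controls", "category", "score",
)


@dataclass
class AnnotatedVariantTable:
    """Validated per-variant carrier counts with functional annotation."""

    data: pd.DataFrame
    n_cases: int
    n_controls: int

    def __len__(self) -> int:
        return len(self.data)


def _fail(line: int, msg: str):
    raise ValueError(f"variant table line {line}: {msg}")


def read_variant_table(path) -> AnnotatedVariantTable:
    """Read and validate a variant-table TSV.

    Raises ``ValueError`` with the offending line number for unknown
    categories, carrier counts exceeding the group size, missing scores on
    predicted variants, or malformed rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(VARIANT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table misses columns: {sorted(missing)}")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        try:
            ca = int(row.cases_carriers)
            co = int(row.controls_carriers)
            n_ca = int(row.n_cases)
            n_co = int(row.n_controls)
        except ValueError:
            _fail(line, "carrier counts and group sizes must be integers")
        if row.category not in CATEGORIES:
            _fail(line, f"unknown category {row.category!r}")
        if ca < 0 or co < 0:
            _fail(line, "carrier counts must be non-negative")
        if ca > n_ca or co > n_co:
            _fail(line, "carrier count exceeds its group size")
        score = np.nan
        if row.score == ".":
            if row.category != "nonsense":
                _fail(line, "score missing on a predicted variant")
        else:
            try:
                score = float(row.score)
            except ValueError:
                _fail(line, f"malformed score {row.score!r}")
        records.append(
            {"variant_id": row.variant_id, "gene": row.gene,
             "cases_carriers": ca, "controls_carriers": co,
             "n_cases": n_ca, "n_controls": n_co,
             "category": row.category, "score": score}
        )
    data = pd.DataFrame.from_records(records, columns=VARIANT_TABLE_COLUMNS)
    if data.empty:
        raise ValueError("variant table holds no variants")
    n_cases = int(data["n_cases"].iloc[0])
    n_controls = int(data["n_controls"].iloc[0])
    if (data["n_cases"] != n_cases).any() or (data["n_controls"] != n_controls).any():
        raise ValueError("group sizes must be constant across the table")
    return AnnotatedVariantTable(data, n_cases, n_controls)


def write_variant_table(table: AnnotatedVariantTable, path) -> None:
    """Write the canonical TSV form (``.`` for missing scores)."""
    df = table.data.copy()
    df["score"] = [
        "." if np.isnan(s) else format(s, "g") for s in df["score"]
    ]
    df.to_csv(path, sep="\t", index=False)


def annotation_to_weights(table: AnnotatedVariantTable):
    """Map categories and PSIC-style scores to test weights (O_l, p_l).

    Benign variants get O = 0, the two damaging categories and nonsense
    variants O = 1.  The continuous weight starts from the quantitative
    score; nonsense variants (unpredictable by PolyPhen) are anchored at
    the highest score observed among the other variants in the grouped
    set.  Scores are then min-max rescaled to [0, 1] across the set, the
    scale the weighted tests expect.  A table of only nonsense variants
    has no score to anchor the maximum and is rejected.
    """
    cat = table.data["category"].to_numpy()
    o = (cat != "benign").astype(np.int8)
    score = table.data["score"].to_numpy(dtype=float).copy()
    predicted = cat != "nonsense"
    if not predicted.any():
        raise ValueError(
            "all variants are nonsense: supply explicit weights instead"
        )
    anchor = float(np.nanmax(score[predicted]))
    score[~predicted] = anchor
    lo, hi = float(score.min()), float(score.max())
    p = np.ones_like(score) if hi == lo else (score - lo) / (hi - lo)
    return o, p


def binomial_damaging_enrichment(k: int, n: int, fp_rate: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, fp_rate).

    Measures how surprising it is to see ``k`` of ``n`` variants called
    damaging if every call were a false positive at the predictor's
    neutral-substitution rate.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 < fp_rate < 1:
        raise ValueError("fp_rate must be in (0, 1)")
    return float(stats.binom.sf(k - 1, n, fp_rate))


def table_to_sample(table: AnnotatedVariantTable, seed=None) -> CaseControlSample:
    """Expand carrier counts into an individual-level genotype matrix.

    Each reported allele is assigned to a distinct heterozygous carrier
    within its group, chosen without replacement under ``seed`` — the
    plausible configuration for rare variants reported as counts.  The
    rare/common partition uses the sample minor-allele frequency at the 1%
    threshold, since population truth is unknown in applied data.
    """
    rng = np.random.default_rng(seed)
    n_ca, n_co = table.n_cases, table.n_controls
    n = n_ca + n_co
    data = table.data
    genotypes = np.zeros((n, len(data)), dtype=np.int8)
    for j, (ca, co) in enumerate(zip(data["cases_carriers"], data["controls_carriers"])):
        if ca:
            genotypes[n_co + rng.choice(n_ca, size=ca, replace=False), j] = 1
        if co:
            genotypes[rng.choice(n_co, size=co, replace=False), j] = 1
    status = np.concatenate([np.zeros(n_co, dtype=int), np.ones(n_ca, dtype=int)])

    freq = (data["cases_carriers"] + data["controls_carriers"]).to_numpy() / (2.0 * n)
    freq = np.clip(freq, 1e-9, 1 - 1e-9)
    panel = VariantPanel(freqs=freq)
    o, p = annotation_to_weights(table)
    panel.functional_binary = o
    panel.functional_score = p
    return CaseControlSample(genotypes=genotypes, status=status, panel=panel)


def analyze_real(table: AnnotatedVariantTable, k: int = 1000, seed=None) -> list[TestResult]:
    """Run all five association tests on an annotated variant table.

    Deterministic given ``(seed, k)``: the carrier-assignment and the
    permutation stream both derive from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_expand, s_test = ss.spawn(2)
    sample = table_to_sample(table, seed=s_expand)
    rng = np.random.default_rng(s_test)
    return run_all_tests(sample, k=k, rng=rng)
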