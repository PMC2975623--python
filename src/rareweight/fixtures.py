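"""Synthetic variant-table generator shaped like pooled sequencing studies.

Emulates the structure of the classic three-gene (ABCA1/APOA1/LCAT)
extreme-HDL sequencing data: two groups of extreme-phenotype individuals,
rare nonsynonymous variants that are almost all exclusive to one group, a
couple of common variants, PolyPhen-style categories with PSIC-like
scores, and an occasional nonsense variant.  Everything is synthetic and
deterministic under the seed; only the published counts structure is
reproduced, not any real genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotatedVariantTable, VARIANT_TABLE_COLUMNS, write_variant_table

__all__ = [
    "FixtureProfile", "dallas_profile", "canada_profile",
    "generate_fixture", "write_fixture",
]


@dataclass(frozen=True)
class FixtureProfile:
    """Shape of a synthetic two-group variant table."""

    n_cases: int = 128
    n_controls: int = 128
    n_case_exclusive_rare: int = 16
    n_control_exclusive_rare: int = 2
    n_common: int = 2
    n_nonsense: int = 1
    damaging_fraction: float = 0.7
    genes: tuple = ("ABCA1", "APOA1", "LCAT")

    def __post_init__(self):
        if min(self.n_cases, self.n_controls) <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_nonsense > self.n_case_exclusive_rare:
            raise ValueError("more nonsense variants than case-exclusive slots")
        if not 0 <= self.damaging_fraction <= 1:
            raise ValueError("damaging_fraction must be in [0, 1]")


def dallas_profile() -> FixtureProfile:
    """128/128 groups, 16 case- and 2 control-exclusive rare, 2 common."""
    return FixtureProfile()


def canada_profile() -> FixtureProfile:
    """155/108 groups, 21 case- and 2 control-exclusive rare, all rare."""
    return FixtureProfile(
        n_cases=155, n_controls=108,
        n_case_exclusive_rare=21, n_control_exclusive_rare=2, n_common=0,
    )


def _psic(rng: np.random.Generator, damaging: bool) -> float:
    """PSIC-like profile score: higher for damaging substitutions."""
    base = rng.uniform(1.8, 3.5) if damaging else rng.uniform(0.1, 1.6)
    return round(base, 3)


def generate_fixture(
    profile: FixtureProfile = FixtureProfile(), seed: int = 0
) -> AnnotatedVariantTable:
    """Build a synthetic annotated variant table under the profile.

    Rare variants are singletons or doubletons exclusive to one group;
    case-exclusive variants are mostly damaging (``damaging_fraction``),
    control-exclusive variants mostly benign; ``n_nonsense`` of the
    case-exclusive variants are protein-truncating (no PSIC score).
    Common variants appear in both groups above 1% frequency.  Output is
    byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    vid = 0

    def add(gene, ca, co, category, score):
        nonlocal vid
        vid += 1
        rows.append({
            "variant_id": f"v{vid:03d}", "gene": gene,
            "cases_carriers": ca, "controls_carriers": co,
            "n_cases": profile.n_cases, "n_controls": profile.n_controls,
            "category": category, "score": score,
        })

    genes = profile.genes
    for i in range(profile.n_case_exclusive_rare):
        gene = genes[i % len(genes)]
        carriers = int(rng.integers(1, 3))
        if i < profile.n_nonsense:
            add(gene, carriers, 0, "nonsense", np.nan)
        elif rng.random() < profile.damaging_fraction:
            cat = "probably_damaging" if rng.random() < 0.6 else "possibly_damaging"
            add(gene, carriers, 0, cat, _psic(rng, True))
        else:
            add(gene, carriers, 0, "benign", _psic(rng, False))
    for i in range(profile.n_control_exclusive_rare):
        gene = genes[i % len(genes)]
        if rng.random() < 1.0 - profile.damaging_fraction:
            cat = "possibly_damaging"
            score = _psic(rng, True)
        else:
            cat = "benign"
            score = _psic(rng, False)
        add(gene, 0, int(rng.integers(1, 3)), cat, score)
    for i in range(profile.n_common):
        gene = genes[i % len(genes)]
        # clearly above the 1% minor-allele threshold in the pooled sample
        lo = max(2, int(0.03 * profile.n_cases))
        ca = int(rng.integers(lo, 2 * lo + 1))
        co = int(rng.integers(max(2, int(0.03 * profile.n_controls)), 2 * lo + 1))
        add(gene, ca, co, "benign", _psic(rng, False))

    data = pd.DataFrame.from_records(rows, columns=VARIANT_TABLE_COLUMNS)
    return AnnotatedVariantTable(data, profile.n_cases, profile.n_controls)


def write_fixture(profile: FixtureProfile, seed: int, path) -> AnnotatedVariantTable:
    """Generate a fixture and write its canonical TSV to ``path``."""
    table = generate_fixture(profile, seed)
    write_variant_table(table, path)
    return table
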