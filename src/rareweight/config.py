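"""YAML configuration loading for the simulation experiments.

Recognised keys (all optional, defaults are the baseline conditions)::

    demography: {N1, Nb, T, rho, scale}
    gene:       {length, syn_fraction, mu_nt}
    pool:       {size}
    sample:     {n_cases, n_controls}
    effect:     {h2, rare_share, f}
    predictor:  {sensitivity, specificity, threshold}
    rng:        {seed}
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .cohort import PhenotypeModel, SamplingDesign
from .demography import DemographicParams, GeneModel
from .evaluation import ExperimentConfig
from .prediction import PredictionProfile

__all__ = ["config_from_dict", "load_config"]


def config_from_dict(raw: dict | None) -> tuple[ExperimentConfig, int | None]:
    """Build an :class:`ExperimentConfig` (plus optional seed) from a dict."""
    raw = raw or {}
    demo = raw.get("demography", {}) or {}
    gene = raw.get("gene", {}) or {}
    pool = raw.get("pool", {}) or {}
    sample = raw.get("sample", {}) or {}
    effect = raw.get("effect", {}) or {}
    pred = raw.get("predictor", {}) or {}
    rng = raw.get("rng", {}) or {}

    config = ExperimentConfig(
        demography=DemographicParams(
            N1=demo.get("N1", 20_000),
            Nb=demo.get("Nb", 14_000),
            T=demo.get("T", 3_300),
            rho=demo.get("rho", 0.001),
        ),
        gene=GeneModel(
            L=gene.get("length", 1_500),
            syn_fraction=gene.get("syn_fraction", 1.0 / 3.0),
            mu_nt=gene.get("mu_nt", 1.8e-8),
        ),
        phenotype=PhenotypeModel(
            h2=effect.get("h2", 0.005),
            rare_share=effect.get("rare_share", 0.9),
        ),
        design=SamplingDesign(
            pool_size=pool.get("size", 50_000),
            n_cases=sample.get("n_cases", 1_000),
            n_controls=sample.get("n_controls", 1_000),
        ),
        predictor=PredictionProfile(
            sensitivity=pred.get("sensitivity", 0.8),
            specificity=pred.get("specificity", 0.15),
            threshold=pred.get("threshold", 0.9),
        ),
        f_causative=effect.get("f", 0.2),
        scale=demo.get("scale", 10.0),
    )
    return config, rng.get("seed")


def load_config(path) -> tuple[ExperimentConfig, int | None]:
    """Load an experiment configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)
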