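"""Simulated functional-prediction measures and the effective proportion.

Prediction algorithms such as PolyPhen or SIFT emit, per variant, a
qualitative call (functional or not) and a quantitative score.  Both are
simulated here from the predictor's operating characteristics.

.. warning::
    Terminology follows the field usage adopted throughout this package:
    *sensitivity* (rho1) is P(called functional | truly causative), but
    *specificity* (rho2) is P(called functional | neutral) — a
    **false-positive rate**, the inverse of the conventional definition of
    specificity.  Keep this in mind when supplying published predictor
    characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import VariantPanel

__all__ = ["PredictionProfile", "simulate_measures", "effective_proportion"]


@dataclass(frozen=True)
class PredictionProfile:
    """Operating characteristics of a functional-prediction algorithm.

    ``sensitivity`` (rho1) and ``specificity`` (rho2, a false-positive
    rate; see the module warning) default to 0.8 and 0.15, midpoints of the
    published ranges for existing predictors (0.69-0.88 and 0.08-0.2).
    ``threshold`` (a) is the continuous-score cut for declaring a variant
    causative, default 0.9.
    """

    sensitivity: float = 0.8
    specificity: float = 0.15
    threshold: float = 0.9

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def simulate_measures(
    panel: VariantPanel,
    profile: PredictionProfile = PredictionProfile(),
    seed=None,
    *,
    rng: np.random.Generator | None = None,
) -> VariantPanel:
    """Draw (O_l, p_l) for every variant in the panel, in place.

    O_l ~ Bernoulli(rho1) for causative variants and Bernoulli(rho2) for
    neutral ones.  Given the call, the continuous measure is uniform on the
    matching side of the threshold: p_l | O_l=1 ~ U[a, 1) and
    p_l | O_l=0 ~ U[0, a).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    prob = np.where(panel.causative, profile.sensitivity, profile.specificity)
    o = (rng.random(panel.n_sites) < prob).astype(np.int8)
    a = profile.threshold
    u = rng.random(panel.n_sites)
    p = np.where(o == 1, a + u * (1.0 - a), u * a)
    panel.functional_binary = o
    panel.functional_score = p
    return panel


def effective_proportion(f: float, rho1: float, rho2: float) -> float:
    """Effective proportion of causative variants after weighting.

    f' = f*rho1 / (f*rho1 + (1-f)*rho2): the expected causative fraction
    among variants the predictor calls functional.  f' > f exactly when
    rho1 > rho2, and f' = f when rho1 = rho2 — weighting only helps when
    the predictor is better than uninformative.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    if not (0 <= rho1 <= 1 and 0 <= rho2 <= 1):
        raise ValueError("rho1 and rho2 must be in [0, 1]")
    denom = f * rho1 + (1.0 - f) * rho2
    if denom == 0:
        raise ZeroDivisionError(
            "effective proportion undefined: no variant is ever called functional"
        )
    return f * rho1 / denom
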