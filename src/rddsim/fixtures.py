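"""Default parameter fixtures for the Dutch online-RDD study population.

Encodes the printed summary statistics of the 2013-2014 Dutch online
respondent-driven detection survey that motivates the simulator's
default scenarios: the marginal characteristics of its 1015 seeds and
433 recruitees, the overall and wave-stratified recruiter-recruitee
mixing proportions, the observed invitation-sending moments and
acceptance probabilities, and a vaccine-belief logistic model.

Two caveats, reflected in the ``approximate`` flags downstream:

* The study's per-recruiter-type invitation parameters and its
  individual-level seed roster were never published; fixtures fall
  back on the overall (or seed/recruitee) moments and on independent
  marginals.
* The belief coefficients are synthetic: effect magnitudes are chosen
  to be plausible (negative beliefs more common among younger, male
  and less academically educated participants) and the intercept is
  calibrated so the population marginal of negative belief matches
  the observed 53.5%.
"""

from __future__ import annotations

import numpy as np

from .population import BeliefModel, SeedSpec

__all__ = [
    "SEED_MARGINALS",
    "RECRUITEE_MARGINALS",
    "OVERALL_MARGINALS",
    "INVITATION_MOMENTS",
    "ACCEPTANCE_PROBS",
    "DEFAULT_C",
    "DEFAULT_CAP",
    "ACTIVE_SEED_TYPE",
    "overall_mixing_tables",
    "wave_mixing_tables",
    "random_mixing_tables",
    "assortative_mixing_tables",
    "default_belief_model",
    "default_seed_spec",
    "sigma2_high",
    "sigma2_low",
]

DEFAULT_C = 4
DEFAULT_CAP = 1000

#: Per-characteristic marginals (order F/M, a1/a2/a3, A/B) of the
#: 1015 wave-0 seeds, the 433 recruitees, and all 1448 participants.
SEED_MARGINALS = {
    "sex": (0.652, 0.348),
    "age_group": (0.125, 0.458, 0.417),
    "education": (0.413, 0.587),
}
RECRUITEE_MARGINALS = {
    "sex": (0.640, 0.360),
    "age_group": (0.279, 0.400, 0.321),
    "education": (0.460, 0.540),
}
OVERALL_MARGINALS = {
    "sex": (0.648, 0.352),
    "age_group": (0.171, 0.441, 0.388),
    "education": (0.427, 0.573),
}

#: Observed mean (variance) of invitations sent, by participant stratum.
INVITATION_MOMENTS = {
    "seed": (1.33, 3.24),
    "recruitee": (1.47, 3.23),
    "overall": (1.36, 3.21),
}

#: Observed proportion of sent invitations that were accepted.
ACCEPTANCE_PROBS = {"seed": 0.189, "recruitee": 0.201, "overall": 0.192}

#: Most active seed profile: female, 60+, academic education.
ACTIVE_SEED_TYPE = ("F", "a3", "B")

#: Negative-belief proportion among all participants.
NEGATIVE_BELIEF_MARGINAL = 0.535


def _rows(*rows) -> np.ndarray:
    """Stack rows and renormalise each to sum exactly to 1 (the printed
    proportions are rounded to two decimals and can sum to 0.99/1.01)."""
    t = np.asarray(rows, dtype=float)
    return t / t.sum(axis=1, keepdims=True)


def overall_mixing_tables() -> dict[str, np.ndarray]:
    """Observed overall mixing proportions (all waves pooled)."""
    return {
        "sex": _rows([0.66, 0.34], [0.58, 0.42]),
        "age_group": _rows(
            [0.60, 0.18, 0.22], [0.26, 0.56, 0.19], [0.19, 0.26, 0.55]
        ),
        "education": _rows([0.65, 0.35], [0.34, 0.66]),
    }


def wave_mixing_tables() -> dict[str, dict[int, np.ndarray]]:
    """Observed mixing proportions stratified by wave band: recruiters
    in wave 0, wave 1, and waves 2+ (waves 2 to 6 pooled)."""
    return {
        "sex": {
            0: _rows([0.61, 0.39], [0.59, 0.41]),
            1: _rows([0.73, 0.27], [0.57, 0.43]),
            2: _rows([0.83, 0.17], [0.50, 0.50]),
        },
        "age_group": {
            0: _rows([0.56, 0.12, 0.31], [0.28, 0.51, 0.21], [0.23, 0.29, 0.49]),
            1: _rows([0.57, 0.29, 0.14], [0.19, 0.67, 0.14], [0.10, 0.21, 0.69]),
            2: _rows([0.86, 0.14, 0.00], [0.20, 0.67, 0.13], [0.07, 0.20, 0.73]),
        },
        "education": {
            0: _rows([0.65, 0.35], [0.35, 0.65]),
            1: _rows([0.67, 0.33], [0.24, 0.76]),
            2: _rows([0.68, 0.31], [0.47, 0.53]),
        },
    }


def random_mixing_tables() -> dict[str, np.ndarray]:
    """Random mixing: rows 0.50 / one-third / 0.50."""
    return {
        "sex": np.full((2, 2), 0.5),
        "age_group": np.full((3, 3), 1.0 / 3.0),
        "education": np.full((2, 2), 0.5),
    }


def assortative_mixing_tables() -> dict[str, np.ndarray]:
    """Strongly assortative variant: females recruit only females and
    academics only academics; males and the lower-education group mix
    randomly; age mixes randomly."""
    return {
        "sex": np.array([[1.0, 0.0], [0.5, 0.5]]),
        "age_group": np.full((3, 3), 1.0 / 3.0),
        "education": np.array([[0.5, 0.5], [0.0, 1.0]]),
    }


def default_belief_model() -> BeliefModel:
    """Synthetic vaccine-belief logistic model (log-odds of negative
    belief).  Effect signs follow the observed pattern of sex and age
    influencing beliefs; the intercept is calibrated so that the exact
    marginal over the overall type distribution is 53.5% negative."""
    return BeliefModel(
        intercept=0.9801015,
        male=0.3,
        age40_59=-0.8,
        age60plus=-1.2,
        academic=-0.2,
    )


def default_seed_spec(count: int = 1015) -> SeedSpec:
    """Seed roster drawn from the observed seed marginals (the joint
    empirical roster is not available; characteristics are drawn
    independently)."""
    return SeedSpec(mode="marginals", count=count, marginals=SEED_MARGINALS)


def sigma2_high(mu: float, c: int = DEFAULT_C) -> float:
    """Near-maximal (bimodal) variance fixture: the observed high
    variance 3.4 where representable, else 95% of the open upper
    variance bound for the given mean."""
    return min(3.4, 0.95 * mu * (c - mu))


def sigma2_low(mu: float, c: int = DEFAULT_C) -> float:
    """Near-minimal (unimodal) variance fixture: 5% above the open
    binomial-floor bound, capped at the observed 1.1."""
    return min(1.1, 1.05 * mu * (1.0 - mu / c))
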