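"""Individuals, recruiter types, mixing and vaccine-belief models.

Participants carry three categorical characteristics — sex (F/M), age
group (0-39 / 40-59 / 60+) and education (lower-than-academic /
academic) — which jointly define 12 recruiter types.  Who a recruiter
tends to invite is described by one row-stochastic conditional table
per characteristic (recruitee category given recruiter category),
assumed independent across the three characteristics; the tables may
additionally vary with the recruiter's wave to capture mixing
behaviour that drifts over successive recruitment waves.

A fourth, dependent covariate — belief about the influenza vaccine
(positive / negative) — is assigned from a logistic model of the three
characteristics and does not feed back into recruitment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._exceptions import ConfigurationError, ParameterError

__all__ = [
    "SEXES",
    "AGE_GROUPS",
    "EDUCATIONS",
    "BELIEFS",
    "CHARACTERISTICS",
    "RECRUITER_TYPES",
    "Individual",
    "recruiter_type",
    "type_from_key",
    "MixingModel",
    "BeliefModel",
    "SeedSpec",
    "draw_recruitee_characteristics",
    "draw_belief",
    "make_seeds",
]

SEXES: tuple[str, ...] = ("F", "M")
AGE_GROUPS: tuple[str, ...] = ("a1", "a2", "a3")  # 0-39, 40-59, 60+
EDUCATIONS: tuple[str, ...] = ("A", "B")  # lower than academic, academic
BELIEFS: tuple[str, ...] = ("positive", "negative")

CHARACTERISTICS: dict[str, tuple[str, ...]] = {
    "sex": SEXES,
    "age_group": AGE_GROUPS,
    "education": EDUCATIONS,
}

#: All 12 recruiter types in a fixed order: (sex, age_group, education).
RECRUITER_TYPES: tuple[tuple[str, str, str], ...] = tuple(
    (s, a, e) for s in SEXES for a in AGE_GROUPS for e in EDUCATIONS
)


@dataclass
class Individual:
    """One participant: a seed (wave 0, no recruiter) or a recruitee."""

    id: str
    recruiter_id: str | None
    wave: int
    sex: str
    age_group: str
    education: str
    belief: str | None = None
    n_sent: int = 0
    n_accepted: int = 0

    def __post_init__(self) -> None:
        if (self.wave == 0) != (self.recruiter_id is None):
            raise ParameterError(
                "wave 0 individuals are exactly the ones without a recruiter"
            )
        if self.sex not in SEXES:
            raise ParameterError(f"unknown sex {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ParameterError(f"unknown age group {self.age_group!r}")
        if self.education not in EDUCATIONS:
            raise ParameterError(f"unknown education {self.education!r}")
        if self.belief is not None and self.belief not in BELIEFS:
            raise ParameterError(f"unknown belief {self.belief!r}")
        if not (0 <= self.n_accepted <= self.n_sent):
            raise ParameterError("need 0 <= n_accepted <= n_sent")


def recruiter_type(ind: Individual) -> str:
    """Type key of an individual, e.g. ``'F.a2.B'``."""
    return f"{ind.sex}.{ind.age_group}.{ind.education}"


def type_from_key(key: str) -> tuple[str, str, str]:
    """Inverse of :func:`recruiter_type`: parse ``'F.a2.B'``."""
    parts = tuple(key.split("."))
    if len(parts) != 3 or parts not in RECRUITER_TYPES:
        raise ParameterError(f"not a recruiter type key: {key!r}")
    return parts


def _check_rows(name: str, cats: Sequence[str], table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    k = len(cats)
    if table.shape != (k, k):
        raise ConfigurationError(
            f"{name} mixing table must be {k}x{k}, got shape {table.shape}"
        )
    if np.any(table < 0):
        raise ConfigurationError(f"{name} mixing table has negative entries")
    sums = table.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9, rtol=0.0):
        raise ConfigurationError(
            f"{name} mixing rows must sum to 1 (got row sums {sums})"
        )
    return table


class MixingModel:
    """Recruiter-conditional recruitee-characteristic distributions.

    For each characteristic, one row-stochastic matrix
    ``P(recruitee category | recruiter category)`` over that
    characteristic's categories (rows = recruiter category, in the
    canonical order of :data:`CHARACTERISTICS`), or a wave-stratified
    set of such matrices with bands ``{0, 1, 2}`` keyed by the
    recruiter's wave; band 2 is reused for all waves >= 2.

    The three characteristics are drawn independently.
    """

    BANDS = (0, 1, 2)

    def __init__(
        self,
        tables: Mapping[str, np.ndarray] | None = None,
        *,
        wave_tables: Mapping[str, Mapping[int, np.ndarray]] | None = None,
    ) -> None:
        if (tables is None) == (wave_tables is None):
            raise ConfigurationError("provide exactly one of tables / wave_tables")
        self._by_band: dict[str, dict[int, np.ndarray]] = {}
        if tables is not None:
            for char, cats in CHARACTERISTICS.items():
                if char not in tables:
                    raise ConfigurationError(f"missing mixing table for {char!r}")
                t = _check_rows(char, cats, np.asarray(tables[char]))
                self._by_band[char] = {b: t for b in self.BANDS}
            self.wave_stratified = False
        else:
            for char, cats in CHARACTERISTICS.items():
                if char not in wave_tables:
                    raise ConfigurationError(f"missing mixing tables for {char!r}")
                per_band = {}
                for b in self.BANDS:
                    if b not in wave_tables[char]:
                        raise ConfigurationError(
                            f"missing wave band {b} for characteristic {char!r}"
                        )
                    per_band[b] = _check_rows(
                        f"{char}[band {b}]", cats, np.asarray(wave_tables[char][b])
                    )
                self._by_band[char] = per_band
            self.wave_stratified = True

    def table(self, characteristic: str, wave: int = 0) -> np.ndarray:
        """Conditional table for a recruiter in the given wave."""
        if characteristic not in CHARACTERISTICS:
            raise ConfigurationError(f"unknown characteristic {characteristic!r}")
        band = min(int(wave), 2)
        return self._by_band[characteristic][band]

    def row(self, characteristic: str, category: str, wave: int = 0) -> np.ndarray:
        """Recruitee distribution given the recruiter's category."""
        cats = CHARACTERISTICS[characteristic]
        if category not in cats:
            raise ConfigurationError(
                f"unknown {characteristic} category {category!r}"
            )
        return self.table(characteristic, wave)[cats.index(category)]

    # -- constructors ---------------------------------------------------
    @classmethod
    def random(cls) -> "MixingModel":
        """Random mixing: recruitee categories uniform, independent of
        the recruiter (rows 0.5 / one-third / 0.5)."""
        return cls(
            tables={
                char: np.full((len(cats), len(cats)), 1.0 / len(cats))
                for char, cats in CHARACTERISTICS.items()
            }
        )

    @classmethod
    def from_marginals(cls, marginals: Mapping[str, Sequence[float]]) -> "MixingModel":
        """Rank-one mixing: recruitee categories drawn from fixed
        marginals regardless of the recruiter."""
        tables = {}
        for char, cats in CHARACTERISTICS.items():
            m = np.asarray(marginals[char], dtype=float)
            m = m / m.sum()
            tables[char] = np.tile(m, (len(cats), 1))
        return cls(tables=tables)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MixingModel):
            return NotImplemented
        return self.wave_stratified == other.wave_stratified and all(
            np.allclose(self._by_band[c][b], other._by_band[c][b], atol=1e-12)
            for c in CHARACTERISTICS
            for b in self.BANDS
        )


def draw_recruitee_characteristics(
    recruiter: Individual,
    mixing: MixingModel,
    wave_of_recruiter: int,
    rng: np.random.Generator,
) -> tuple[str, str, str]:
    """Draw a recruitee's (sex, age_group, education) given its recruiter.

    Three independent categorical draws from the recruiter-conditional
    rows of the mixing model, using the recruiter's wave to resolve the
    wave band.
    """
    out = []
    for char, cats in CHARACTERISTICS.items():
        row = mixing.row(char, getattr(recruiter, char), wave_of_recruiter)
        out.append(cats[rng.choice(len(cats), p=row)])
    return tuple(out)  # type: ignore[return-value]


@dataclass(frozen=True)
class BeliefModel:
    """Logistic model for the probability of a *negative* vaccine belief.

    The linear predictor is, on the log-odds scale,
    ``intercept + male*[sex=M] + age40_59*[a2] + age60plus*[a3]
    + academic*[education=B]`` with females, ages 0-39 and
    lower-than-academic education as the reference categories.
    """

    intercept: float = 0.0
    male: float = 0.0
    age40_59: float = 0.0
    age60plus: float = 0.0
    academic: float = 0.0

    def log_odds(self, sex: str, age_group: str, education: str) -> float:
        if sex not in SEXES or age_group not in AGE_GROUPS or education not in EDUCATIONS:
            raise ParameterError(
                f"unknown categories ({sex!r}, {age_group!r}, {education!r})"
            )
        return (
            self.intercept
            + (self.male if sex == "M" else 0.0)
            + (self.age40_59 if age_group == "a2" else 0.0)
            + (self.age60plus if age_group == "a3" else 0.0)
            + (self.academic if education == "B" else 0.0)
        )

    def prob_negative(self, sex: str, age_group: str, education: str) -> float:
        return 1.0 / (1.0 + math.exp(-self.log_odds(sex, age_group, education)))

    def marginal_negative(self, type_probs: Mapping[tuple[str, str, str], float]) -> float:
        """Population marginal of negative belief under a distribution
        over the 12 recruiter types (exact marginalisation)."""
        total = sum(type_probs.values())
        return (
            sum(
                w * self.prob_negative(*t)
                for t, w in type_probs.items()
            )
            / total
        )


def draw_belief(
    sex: str,
    age_group: str,
    education: str,
    model: BeliefModel,
    rng: np.random.Generator,
) -> str:
    """Bernoulli draw of a vaccine belief from the logistic model."""
    p_neg = model.prob_negative(sex, age_group, education)
    return "negative" if rng.random() < p_neg else "positive"


@dataclass(frozen=True)
class SeedSpec:
    """Specification of the wave-0 seed set.

    Modes
    -----
    ``marginals``
        Draw each seed's three characteristics independently from the
        given per-characteristic marginals.
    ``roster``
        Use an explicit list of (sex, age_group, education) tuples,
        recycled or truncated to ``count``.
    ``active``
        All seeds share one designated high-activity type.
    """

    mode: str
    count: int
    marginals: Mapping[str, Sequence[float]] | None = None
    roster: Sequence[tuple[str, str, str]] | None = None
    active_type: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("marginals", "roster", "active"):
            raise ConfigurationError(f"unknown seed mode {self.mode!r}")
        if self.count < 1:
            raise ConfigurationError(f"seed count must be >= 1, got {self.count}")
        if self.mode == "marginals":
            if self.marginals is None:
                raise ConfigurationError("marginals mode needs marginal distributions")
            for char, cats in CHARACTERISTICS.items():
                m = np.asarray(self.marginals[char], dtype=float)
                if m.shape != (len(cats),) or np.any(m < 0) or not np.isclose(m.sum(), 1.0, atol=1e-9):
                    raise ConfigurationError(
                        f"seed marginal for {char!r} must be a probability vector "
                        f"over {cats}"
                    )
        if self.mode == "roster" and not self.roster:
            raise ConfigurationError("roster mode needs a non-empty roster")
        if self.mode == "active" and self.active_type not in RECRUITER_TYPES:
            raise ConfigurationError(
                f"active mode needs a valid recruiter type, got {self.active_type!r}"
            )


def make_seeds(
    spec: SeedSpec,
    rng: np.random.Generator,
    belief_model: BeliefModel | None = None,
    id_prefix: str = "s",
) -> list[Individual]:
    """Construct the wave-0 seed individuals for one simulated data set."""
    types: list[tuple[str, str, str]]
    if spec.mode == "marginals":
        assert spec.marginals is not None
        draws = {}
        for char, cats in CHARACTERISTICS.items():
            m = np.asarray(spec.marginals[char], dtype=float)
            draws[char] = rng.choice(len(cats), size=spec.count, p=m / m.sum())
        types = [
            (SEXES[draws["sex"][i]], AGE_GROUPS[draws["age_group"][i]], EDUCATIONS[draws["education"][i]])
            for i in range(spec.count)
        ]
    elif spec.mode == "roster":
        assert spec.roster is not None
        roster = list(spec.roster)
        types = [roster[i % len(roster)] for i in range(spec.count)]
    else:
        assert spec.active_type is not None
        types = [spec.active_type] * spec.count

    seeds = []
    for i, (s, a, e) in enumerate(types):
        belief = draw_belief(s, a, e, belief_model, rng) if belief_model else None
        seeds.append(
            Individual(
                id=f"{id_prefix}{i}",
                recruiter_id=None,
                wave=0,
                sex=s,
                age_group=a,
                education=e,
                belief=belief,
            )
        )
    return seeds
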