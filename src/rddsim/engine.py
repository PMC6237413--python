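"""Wave-synchronous simulation of recruitment trees.

One run starts from a single seed in wave 0.  Every member of wave W
draws a number of invitations to send from its recruiter type's
beta-binomial distribution, each sent invitation is accepted
independently with the type's acceptance probability, and every
accepted invitation creates a wave W+1 recruitee whose characteristics
are drawn from the mixing model conditional on the recruiter.  The run
stops when a wave sends no invitations, when none of the sent
invitations is accepted, or when the cumulative number of recruitees
reaches the cap N after a wave completes (the wave that crosses the
cap is retained in full; the cap truncates further recruitment, not
the wave itself).

Waves are processed as vectorised blocks, so large trees (the cap
defaults to 1000 recruitees) cost a handful of array operations per
wave rather than per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, ParameterError
from .distributions import BetaBinomialParams, PointMass
from .population import (
    AGE_GROUPS,
    BELIEFS,
    CHARACTERISTICS,
    EDUCATIONS,
    RECRUITER_TYPES,
    SEXES,
    BeliefModel,
    Individual,
    MixingModel,
)

__all__ = [
    "TypeParams",
    "RecruiterTypeTable",
    "RunConfig",
    "RecruitmentTree",
    "simulate_tree",
    "simulate_batch",
    "trees_to_edge_frame",
    "trees_to_summary_frame",
]

_TYPE_KEYS = tuple(f"{s}.{a}.{e}" for (s, a, e) in RECRUITER_TYPES)


def _type_index(sex_code: np.ndarray, age_code: np.ndarray, edu_code: np.ndarray) -> np.ndarray:
    return sex_code * 6 + age_code * 2 + edu_code


@dataclass(frozen=True)
class TypeParams:
    """Recruitment parameters of one recruiter type."""

    invitations: BetaBinomialParams | PointMass
    acceptance: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.acceptance <= 1.0):
            raise ParameterError(
                f"acceptance probability must be in [0, 1], got {self.acceptance}"
            )


class RecruiterTypeTable:
    """Per-type invitation and acceptance parameters.

    Either homogeneous (one parameter set for everyone), stratified by
    the 12 recruiter types, and/or stratified by seed vs recruitee
    status (some surveys show seeds sending systematically fewer
    invitations than later-wave recruitees).
    """

    def __init__(
        self,
        recruitee: Mapping[str, TypeParams] | TypeParams,
        seed: Mapping[str, TypeParams] | TypeParams | None = None,
    ) -> None:
        self._recruitee = self._expand(recruitee)
        self._seed = self._expand(seed) if seed is not None else self._recruitee
        self.seed_stratified = seed is not None

    @staticmethod
    def _expand(entry: Mapping[str, TypeParams] | TypeParams) -> tuple[TypeParams, ...]:
        if isinstance(entry, TypeParams):
            return tuple(entry for _ in _TYPE_KEYS)
        missing = [k for k in _TYPE_KEYS if k not in entry]
        if missing:
            raise ConfigurationError(f"type table missing recruiter types: {missing}")
        return tuple(entry[k] for k in _TYPE_KEYS)

    @classmethod
    def homogeneous(
        cls,
        invitations: BetaBinomialParams | PointMass,
        acceptance: float,
        *,
        seed_invitations: BetaBinomialParams | PointMass | None = None,
        seed_acceptance: float | None = None,
    ) -> "RecruiterTypeTable":
        rec = TypeParams(invitations, acceptance)
        seed = None
        if seed_invitations is not None or seed_acceptance is not None:
            seed = TypeParams(
                seed_invitations if seed_invitations is not None else invitations,
                seed_acceptance if seed_acceptance is not None else acceptance,
            )
        return cls(rec, seed)

    def params_for(self, type_key: str, *, is_seed: bool = False) -> TypeParams:
        if type_key not in _TYPE_KEYS:
            raise ConfigurationError(f"unknown recruiter type {type_key!r}")
        table = self._seed if is_seed else self._recruitee
        return table[_TYPE_KEYS.index(type_key)]

    def stratum(self, *, is_seed: bool) -> tuple[TypeParams, ...]:
        return self._seed if is_seed else self._recruitee

    @property
    def c(self) -> int:
        cs = {tp.invitations.c for tp in self._recruitee + self._seed}
        if len(cs) != 1:
            raise ConfigurationError(f"inconsistent max coupon counts in table: {cs}")
        return cs.pop()


@dataclass
class RunConfig:
    """Everything one simulation run needs besides the seed and the RNG."""

    types: RecruiterTypeTable
    mixing: MixingModel
    belief: BeliefModel | None = None
    cap: int = 1000

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise ConfigurationError(f"cap N must be >= 1, got {self.cap}")

    @property
    def c(self) -> int:
        return self.types.c


class RecruitmentTree:
    """One seed plus all recruitees reachable through recruitment links.

    Recruitees are stored as parallel arrays (wave, recruiter index,
    category codes, sent/accepted counts); the seed is kept as an
    :class:`~rddsim.population.Individual` with its own sent/accepted
    counts filled in.  Recruiter index ``-1`` denotes the seed.
    """

    def __init__(
        self,
        seed: Individual,
        *,
        wave: np.ndarray,
        recruiter_index: np.ndarray,
        sex_code: np.ndarray,
        age_code: np.ndarray,
        edu_code: np.ndarray,
        belief_code: np.ndarray,
        n_sent: np.ndarray,
        n_accepted: np.ndarray,
        stop_reason: str,
    ) -> None:
        self.seed = seed
        self.wave = wave
        self.recruiter_index = recruiter_index
        self.sex_code = sex_code
        self.age_code = age_code
        self.edu_code = edu_code
        self.belief_code = belief_code
        self.n_sent = n_sent
        self.n_accepted = n_accepted
        self.stop_reason = stop_reason

    # -- summary properties --------------------------------------------
    @property
    def size(self) -> int:
        """Number of recruitees (the seed is not counted)."""
        return int(self.wave.size)

    @property
    def max_wave(self) -> int:
        """Highest wave index holding at least one recruitee (0 if none)."""
        return int(self.wave.max()) if self.wave.size else 0

    def wave_sizes(self) -> np.ndarray:
        """Recruitee counts per wave, index 1..max_wave (index 0 is 0)."""
        if not self.wave.size:
            return np.zeros(1, dtype=np.int64)
        return np.bincount(self.wave)

    def recruitee_id(self, i: int) -> str:
        return f"{self.seed.id}.{i + 1}"

    def edges(self) -> list[tuple[str, str]]:
        """(recruiter id, recruitee id) pairs."""
        out = []
        for i, r in enumerate(self.recruiter_index):
            rid = self.seed.id if r < 0 else self.recruitee_id(int(r))
            out.append((rid, self.recruitee_id(i)))
        return out

    def recruitees(self) -> Iterator[Individual]:
        """Recruitees as Individual objects (materialised lazily)."""
        for i in range(self.size):
            r = int(self.recruiter_index[i])
            b = int(self.belief_code[i])
            yield Individual(
                id=self.recruitee_id(i),
                recruiter_id=self.seed.id if r < 0 else self.recruitee_id(r),
                wave=int(self.wave[i]),
                sex=SEXES[self.sex_code[i]],
                age_group=AGE_GROUPS[self.age_code[i]],
                education=EDUCATIONS[self.edu_code[i]],
                belief=None if b < 0 else BELIEFS[b],
                n_sent=int(self.n_sent[i]),
                n_accepted=int(self.n_accepted[i]),
            )

    def all_individuals(self) -> Iterator[Individual]:
        yield self.seed
        yield from self.recruitees()

    def frame(self) -> pd.DataFrame:
        """Recruitees (seed included as wave 0) as a tidy DataFrame."""
        rows = [
            {
                "recruitee_id": ind.id,
                "recruiter_id": ind.recruiter_id if ind.recruiter_id else "",
                "wave": ind.wave,
                "sex": ind.sex,
                "age_group": ind.age_group,
                "education": ind.education,
                "belief": ind.belief if ind.belief else "",
                "n_sent": ind.n_sent,
                "n_accepted": ind.n_accepted,
            }
            for ind in self.all_individuals()
        ]
        return pd.DataFrame(rows)

    def composition_counts(self) -> np.ndarray:
        """Per-wave tallies used by the outcome statistics.

        Returns an array of shape ``(max_wave + 1, 5)`` with columns
        (total, female, age 60+, academic, negative belief); wave 0 is
        the seed.
        """
        n_waves = self.max_wave + 1
        out = np.zeros((n_waves, 5), dtype=np.int64)
        out[0, 0] = 1
        out[0, 1] = 1 if self.seed.sex == "F" else 0
        out[0, 2] = 1 if self.seed.age_group == "a3" else 0
        out[0, 3] = 1 if self.seed.education == "B" else 0
        out[0, 4] = 1 if self.seed.belief == "negative" else 0
        if self.wave.size:
            np.add.at(out[:, 0], self.wave, 1)
            np.add.at(out[:, 1], self.wave, (self.sex_code == 0).astype(np.int64))
            np.add.at(out[:, 2], self.wave, (self.age_code == 2).astype(np.int64))
            np.add.at(out[:, 3], self.wave, (self.edu_code == 1).astype(np.int64))
            np.add.at(out[:, 4], self.wave, (self.belief_code == 1).astype(np.int64))
        return out


def _categorical(cum_row: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised categorical draw via inverse transform."""
    return np.searchsorted(cum_row, rng.random(size), side="right").astype(np.int8)


def _validate_tree_invariants(tree: RecruitmentTree, cap: int, c: int) -> None:
    w, r = tree.wave, tree.recruiter_index
    if w.size == 0:
        return
    parent_wave = np.where(r < 0, 0, w[np.maximum(r, 0)])
    if not np.all(w == parent_wave + 1):
        raise AssertionError("recruitee wave must equal recruiter wave + 1")
    if np.any(tree.n_accepted > tree.n_sent) or np.any(tree.n_sent > c):
        raise AssertionError("need n_accepted <= n_sent <= c")


def simulate_tree(
    seed: Individual,
    cfg: RunConfig,
    rng: np.random.Generator,
    *,
    check: bool = False,
) -> RecruitmentTree:
    """Simulate one recruitment tree from a single seed."""
    if seed.wave != 0 or seed.recruiter_id is not None:
        raise ConfigurationError("the starting individual must be a wave-0 seed")
    c = cfg.c
    belief = cfg.belief

    # per-stratum parameter lookups, aligned with the 12 type codes
    strata = {
        True: cfg.types.stratum(is_seed=True),
        False: cfg.types.stratum(is_seed=False),
    }
    p_neg = None
    if belief is not None:
        p_neg = np.array(
            [belief.prob_negative(s, a, e) for (s, a, e) in RECRUITER_TYPES]
        )

    # cumulative mixing rows cached per (characteristic, wave band)
    char_names = tuple(CHARACTERISTICS)
    cum_rows = {}

    def cum_table(char: str, wave: int) -> np.ndarray:
        band = min(wave, 2)
        key = (char, band)
        if key not in cum_rows:
            cum_rows[key] = np.cumsum(cfg.mixing.table(char, wave), axis=1)
        return cum_rows[key]

    # current-wave state (wave 0 = the seed)
    sex_w = np.array([SEXES.index(seed.sex)], dtype=np.int8)
    age_w = np.array([AGE_GROUPS.index(seed.age_group)], dtype=np.int8)
    edu_w = np.array([EDUCATIONS.index(seed.education)], dtype=np.int8)
    index_w = np.array([-1], dtype=np.int64)  # global recruitee index; -1 = seed

    chunks: dict[str, list[np.ndarray]] = {
        k: [] for k in ("wave", "recruiter", "sex", "age", "edu", "belief", "sent", "acc")
    }
    sent_store: list[np.ndarray] = []  # aligned with recruitee chunks
    acc_store: list[np.ndarray] = []
    seed_sent = seed_acc = 0
    total = 0
    wave = 0
    stop_reason = None

    while True:
        m = sex_w.size
        type_idx = _type_index(sex_w, age_w, edu_w)
        params = strata[wave == 0]

        n_sent = np.zeros(m, dtype=np.int64)
        p_acc = np.empty(m, dtype=float)
        for t in np.unique(type_idx):
            mask = type_idx == t
            tp = params[int(t)]
            n_sent[mask] = tp.invitations.sample(int(mask.sum()), rng)
            p_acc[mask] = tp.acceptance
        n_acc = rng.binomial(n_sent, p_acc)

        # write back the sending behaviour of this wave's members
        if wave == 0:
            seed_sent, seed_acc = int(n_sent[0]), int(n_acc[0])
        else:
            sent_store[-1][:] = n_sent
            acc_store[-1][:] = n_acc

        if n_sent.sum() == 0:
            stop_reason = "no_invitations"
            break
        if n_acc.sum() == 0:
            stop_reason = "none_accepted"
            break

        # build wave W+1
        n_children = int(n_acc.sum())
        parent_local = np.repeat(np.arange(m), n_acc)
        child_recruiter = index_w[parent_local]
        parent_codes = {"sex": sex_w, "age_group": age_w, "education": edu_w}
        child_codes = {}
        for char, cats in CHARACTERISTICS.items():
            cum = cum_table(char, wave)
            pc = parent_codes[char][parent_local]
            cc = np.empty(n_children, dtype=np.int8)
            for v in range(len(cats)):
                mask = pc == v
                k = int(mask.sum())
                if k:
                    cc[mask] = _categorical(cum[v], k, rng)
            child_codes[char] = cc
        if p_neg is not None:
            ct = _type_index(
                child_codes["sex"], child_codes["age_group"], child_codes["education"]
            )
            child_belief = (rng.random(n_children) < p_neg[ct]).astype(np.int8)
        else:
            child_belief = np.full(n_children, -1, dtype=np.int8)

        chunks["wave"].append(np.full(n_children, wave + 1, dtype=np.int64))
        chunks["recruiter"].append(child_recruiter)
        chunks["sex"].append(child_codes["sex"])
        chunks["age"].append(child_codes["age_group"])
        chunks["edu"].append(child_codes["education"])
        chunks["belief"].append(child_belief)
        sent_chunk = np.zeros(n_children, dtype=np.int64)
        acc_chunk = np.zeros(n_children, dtype=np.int64)
        sent_store.append(sent_chunk)
        acc_store.append(acc_chunk)

        child_index = np.arange(total, total + n_children, dtype=np.int64)
        total += n_children
        if total >= cfg.cap:
            stop_reason = "cap_exceeded"
            break

        sex_w = child_codes["sex"]
        age_w = child_codes["age_group"]
        edu_w = child_codes["education"]
        index_w = child_index
        wave += 1

    def cat(key: str, dtype) -> np.ndarray:
        parts = chunks[key]
        return np.concatenate(parts) if parts else np.empty(0, dtype=dtype)

    tree = RecruitmentTree(
        seed=replace(seed, n_sent=seed_sent, n_accepted=seed_acc),
        wave=cat("wave", np.int64),
        recruiter_index=cat("recruiter", np.int64),
        sex_code=cat("sex", np.int8),
        age_code=cat("age", np.int8),
        edu_code=cat("edu", np.int8),
        belief_code=cat("belief", np.int8),
        n_sent=np.concatenate(sent_store) if sent_store else np.empty(0, np.int64),
        n_accepted=np.concatenate(acc_store) if acc_store else np.empty(0, np.int64),
        stop_reason=stop_reason,
    )
    if check:
        _validate_tree_invariants(tree, cfg.cap, c)
    return tree


SeedFactory = Callable[[np.random.Generator], Sequence[Individual]]


def simulate_batch(
    seeds: Sequence[Individual] | SeedFactory,
    cfg: RunConfig,
    n_runs: int,
    master_seed: int = 0,
) -> list[list[RecruitmentTree]]:
    """Simulate ``n_runs`` replicate data sets.

    One simulated data set is the collection of recruitment trees grown
    from one full seed roster.  ``seeds`` is either a fixed roster
    reused in every data set, or a callable ``rng -> roster`` invoked
    once per data set (so the roster itself is re-drawn each replicate).

    Reproducibility: every random stream is derived from ``master_seed``
    by a documented counter scheme — the roster of data set ``d`` uses
    ``SeedSequence(master_seed, spawn_key=(d, 0))`` and the tree of
    seed ``i`` in data set ``d`` uses
    ``SeedSequence(master_seed, spawn_key=(d, i + 1))``.  Identical
    master seeds give identical outputs, independent of execution
    order.
    """
    if n_runs < 1:
        raise ConfigurationError(f"n_runs must be >= 1, got {n_runs}")
    datasets = []
    for d in range(n_runs):
        if callable(seeds):
            roster_rng = np.random.default_rng(
                np.random.SeedSequence(master_seed, spawn_key=(d, 0))
            )
            roster = seeds(roster_rng)
        else:
            roster = seeds
        trees = []
        for i, seed in enumerate(roster):
            rng = np.random.default_rng(
                np.random.SeedSequence(master_seed, spawn_key=(d, i + 1))
            )
            trees.append(simulate_tree(seed, cfg, rng))
        datasets.append(trees)
    return datasets


def trees_to_edge_frame(
    datasets: Sequence[Sequence[RecruitmentTree]],
) -> pd.DataFrame:
    """Edge-list export of all trees: one row per individual."""
    frames = []
    for d, trees in enumerate(datasets):
        for t, tree in enumerate(trees):
            f = tree.frame()
            f.insert(0, "tree_id", tree.seed.id)
            f.insert(0, "run", t)
            f.insert(0, "dataset", d)
            frames.append(f)
    return pd.concat(frames, ignore_index=True)


def trees_to_summary_frame(
    datasets: Sequence[Sequence[RecruitmentTree]],
) -> pd.DataFrame:
    """Per-tree summary: size, deepest wave, stop reason."""
    rows = [
        {
            "dataset": d,
            "run": t,
            "tree_id": tree.seed.id,
            "size": tree.size,
            "max_wave": tree.max_wave,
            "stop_reason": tree.stop_reason,
        }
        for d, trees in enumerate(datasets)
        for t, tree in enumerate(trees)
    ]
    return pd.DataFrame(rows)
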