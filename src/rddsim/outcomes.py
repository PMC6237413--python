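"""Outcome statistics over collections of recruitment trees.

Covers the success and convergence measures of a recruitment study:
the proportion of runs yielding a "large" tree (size at least the cap
N, operationalising sustained recruitment), the distribution of the
deepest wave reached, the per-wave sample composition averaged over
replicate data sets, the wave at which that composition stabilises
(consecutive relative change below 2%), and recruiter-recruitee
mixing correlations with the conventional assortativity bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ParameterError, UndefinedStatisticError
from .engine import RecruitmentTree

__all__ = [
    "CATEGORIES",
    "CompositionSeries",
    "large_tree_proportion",
    "threshold_flag",
    "wave_distribution",
    "composition_series",
    "equilibrium_wave",
    "mixing_correlation",
    "classify_mixing",
    "recruitment_pairs",
]

#: Reported composition categories: share of females, of the 60+ age
#: group, of academically educated participants and of negative
#: vaccine beliefs.
CATEGORIES = ("female", "age_60plus", "academic", "negative_belief")


def large_tree_proportion(trees: Sequence[RecruitmentTree], N: int = 1000) -> float:
    """Fraction of trees whose recruitee count reaches N (boundary
    inclusive: a tree of exactly N recruitees is large)."""
    trees = list(trees)
    if not trees:
        raise ParameterError("need at least one tree")
    return sum(t.size >= N for t in trees) / len(trees)


def threshold_flag(proportion: float, threshold: float = 0.05) -> bool:
    """Whether at least 5% of runs produced a large tree."""
    return proportion >= threshold


def wave_distribution(trees: Sequence[RecruitmentTree]) -> pd.Series:
    """Histogram of the deepest wave reached per tree."""
    trees = list(trees)
    if not trees:
        raise ParameterError("need at least one tree")
    waves = pd.Series([t.max_wave for t in trees])
    return waves.value_counts().sort_index()


@dataclass(frozen=True)
class CompositionSeries:
    """Per-wave category proportions averaged over simulated data sets.

    ``proportions`` has one row per wave and one column per category in
    :data:`CATEGORIES`; ``counts`` carries the mean per-wave
    denominator and ``n_datasets`` the number of data sets contributing
    to each wave (data sets with an empty wave are excluded from that
    wave's average).
    """

    proportions: pd.DataFrame
    counts: pd.Series
    n_datasets: pd.Series

    def series(self, category: str) -> np.ndarray:
        return self.proportions[category].to_numpy()


def composition_series(
    datasets: Sequence[Sequence[RecruitmentTree]],
    *,
    max_wave: int | None = None,
) -> CompositionSeries:
    """Mean per-wave sample composition across replicate data sets.

    Proportions are computed per wave within each data set (pooling
    all of its trees, seeds included at wave 0) and then averaged over
    data sets, weighting each data set equally.  Data sets with an
    empty wave are excluded from that wave's average (dropped, not
    imputed).

    ``max_wave`` truncates the series: the deepest waves of a capped
    simulation are reached by only a handful of slow-growing trees, so
    their across-dataset means are dominated by tiny denominators;
    convergence questions are usually asked over the first ~10 waves
    where every replicate contributes.
    """
    datasets = [list(d) for d in datasets]
    if not datasets or not all(datasets):
        raise ParameterError("need at least one data set of trees")

    deepest = max(t.max_wave for d in datasets for t in d)
    max_wave = deepest if max_wave is None else min(max_wave, deepest)
    n_w, k = max_wave + 1, len(CATEGORIES)
    prop_sum = np.zeros((n_w, k))
    contrib = np.zeros(n_w)
    count_sum = np.zeros(n_w)
    for d in datasets:
        tallies = np.zeros((n_w, 5))
        for tree in d:
            c = tree.composition_counts()[:n_w]
            tallies[: c.shape[0]] += c
        present = tallies[:, 0] > 0
        prop_sum[present] += tallies[present, 1:] / tallies[present, :1]
        contrib += present
        count_sum += tallies[:, 0]

    observed = contrib > 0
    waves = np.arange(n_w)[observed]
    props = prop_sum[observed] / contrib[observed, None]
    return CompositionSeries(
        proportions=pd.DataFrame(props, index=waves, columns=list(CATEGORIES)),
        counts=pd.Series(count_sum[observed] / len(datasets), index=waves),
        n_datasets=pd.Series(contrib[observed].astype(int), index=waves),
    )


def equilibrium_wave(
    series,
    tol: float = 0.02,
    *,
    mode: Literal["all", "first"] = "all",
) -> int | None:
    """Wave from which the composition is considered stable.

    A consecutive pair of waves (W, W+1) is *stable* when the relative
    change ``|p[W+1] - p[W]| / p[W]`` is below ``tol`` (2% by
    convention); a pair with ``p[W] = 0`` has an undefined relative
    change and counts as unstable.  With ``mode='all'`` (default) the
    equilibrium wave is the smallest W such that every later observed
    pair is stable — robust against a single coincidentally small
    change; ``mode='first'`` takes the first stable pair.

    Accepts a plain 1-D sequence of per-wave proportions.  Returns
    ``None`` when no such wave exists within the observed range.
    """
    p = np.asarray(series, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ParameterError("need a 1-D series with at least two waves")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(np.diff(p)) / p[:-1]
    stable = np.isfinite(rel) & (rel < tol)
    if mode == "first":
        idx = np.flatnonzero(stable)
        return int(idx[0]) if idx.size else None
    if mode != "all":
        raise ParameterError(f"unknown mode {mode!r}")
    # smallest W with all pairs from W on stable
    unstable = np.flatnonzero(~stable)
    w = 0 if unstable.size == 0 else int(unstable[-1]) + 1
    return w if w < p.size - 1 or unstable.size == 0 else None


def recruitment_pairs(
    trees: Sequence[RecruitmentTree], characteristic: str
) -> list[tuple[str, str]]:
    """(recruiter category, recruitee category) pairs across all
    recruitment edges of the given trees."""
    from .population import AGE_GROUPS, EDUCATIONS, SEXES

    labels = {"sex": SEXES, "age_group": AGE_GROUPS, "education": EDUCATIONS}[
        characteristic
    ]
    code_attr = {"sex": "sex_code", "age_group": "age_code", "education": "edu_code"}[
        characteristic
    ]
    pairs = []
    for tree in trees:
        codes = getattr(tree, code_attr)
        seed_cat = getattr(tree.seed, characteristic)
        for i, r in enumerate(tree.recruiter_index):
            parent = seed_cat if r < 0 else labels[codes[int(r)]]
            pairs.append((parent, labels[codes[i]]))
    return pairs


def mixing_correlation(
    pairs: Sequence[tuple],
    *,
    kind: Literal["binary", "ordinal"] = "binary",
) -> float:
    """Recruiter-recruitee correlation for one characteristic.

    Binary characteristics (sex, education, belief) use the phi
    coefficient — the Pearson correlation of the 0/1-coded pair list;
    the ordered age variable uses the Spearman rank correlation.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ParameterError("need at least two recruiter-recruitee pairs")
    a, b = zip(*pairs)
    cat_a, cat_b = sorted(set(a) | set(b)), sorted(set(a) | set(b))
    xa = np.array([cat_a.index(v) for v in a], dtype=float)
    xb = np.array([cat_b.index(v) for v in b], dtype=float)
    if xa.std() == 0 or xb.std() == 0:
        raise UndefinedStatisticError(
            "mixing correlation undefined: a margin has zero variance"
        )
    if kind == "binary":
        if len(cat_a) > 2:
            raise ParameterError("phi coefficient needs a binary characteristic")
        r = stats.pearsonr(xa, xb).statistic
    elif kind == "ordinal":
        r = stats.spearmanr(xa, xb).statistic
    else:
        raise ParameterError(f"unknown correlation kind {kind!r}")
    return float(r)


def classify_mixing(r: float, band: float = 0.10) -> str:
    """Conventional assortativity bands: correlations above +0.10 are
    assortative, below -0.10 disassortative, else random."""
    if r > band:
        return "assortative"
    if r < -band:
        return "disassortative"
    return "random"
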