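"""Branching-process theory companion to the simulator.

The number of *accepted* invitations per recruiter is the offspring
distribution of a Galton-Watson process; its mean ``m = mu * p`` (mean
invitations sent times acceptance probability) is the reproduction
number of recruitment.  The probability that a recruitment tree stays
finite is the extinction probability ``q``, the smallest fixed point
of the offspring probability generating function ``G`` on ``[0, 1]``;
``q = 1`` exactly when ``m <= 1`` (barring the degenerate single-child
case), so ``m = 1`` is the threshold separating parameter sets that
can only produce small trees from those that can sustain recruitment.

These closed-form quantities serve both as independent oracles for the
simulator and as a fast design tool: ``1 - q`` approximates (and
upper-bounds) the simulated proportion of trees that reach the size
cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._exceptions import ConfigurationError, ParameterError
from .distributions import BetaBinomialParams, PointMass
from .population import CHARACTERISTICS, RECRUITER_TYPES, MixingModel

__all__ = [
    "OffspringDistribution",
    "offspring_pmf",
    "extinction_probability",
    "large_tree_probability",
    "critical_boundary",
    "markov_composition",
    "mean_offspring_matrix",
    "spectral_radius",
]


@dataclass(frozen=True)
class OffspringDistribution:
    """Pmf of the number of accepted invitations per recruiter."""

    pmf: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.pmf)
        if p.size < 1 or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError("offspring pmf must be non-negative and sum to 1")

    @property
    def c(self) -> int:
        return len(self.pmf) - 1

    @property
    def mean(self) -> float:
        return float(np.dot(np.arange(len(self.pmf)), self.pmf))

    def pgf(self, s: float | np.ndarray) -> float | np.ndarray:
        """Probability generating function ``G(s) = E[s^K]`` (Horner)."""
        out = 0.0
        for pk in reversed(self.pmf):
            out = out * s + pk
        return out


def offspring_pmf(
    params: BetaBinomialParams | PointMass, p: float
) -> OffspringDistribution:
    """Offspring distribution: beta-binomial sending thinned by acceptance.

    ``P(K = k) = sum_{n >= k} P(sent = n) * C(n, k) p^k (1-p)^(n-k)``.
    """
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"acceptance probability must be in [0, 1], got {p}")
    sent = params.pmf_vector()
    c = len(sent) - 1
    out = np.zeros(c + 1)
    for n in range(c + 1):
        if sent[n] > 0:
            out[: n + 1] += sent[n] * stats.binom.pmf(np.arange(n + 1), n, p)
    out = np.clip(out, 0.0, None)
    out /= out.sum()
    return OffspringDistribution(pmf=tuple(out))


def extinction_probability(
    d: OffspringDistribution, *, tol: float = 1e-12, max_iter: int = 10_000_000
) -> float:
    """Smallest fixed point of the offspring PGF on ``[0, 1]``.

    Solved by monotone fixed-point iteration ``q <- G(q)`` from 0,
    which converges increasingly to the smallest root.  By the
    branching-process threshold theorem the answer is exactly 1 when
    the offspring mean is at most 1 (excluding the degenerate
    ``P(K=1) = 1`` case, for which the smallest fixed point is 0), so
    those branches are returned directly rather than approached
    asymptotically.
    """
    pmf = np.asarray(d.pmf)
    if len(pmf) > 1 and abs(pmf[1] - 1.0) < 1e-15:
        return 0.0
    if d.mean <= 1.0:
        return 1.0
    q = 0.0
    for _ in range(max_iter):
        q_next = float(d.pgf(q))
        if q_next < q - 1e-15:
            raise AssertionError("fixed-point iteration must be monotone increasing")
        if q_next - q < tol:
            return q_next
        q = q_next
    raise RuntimeError("extinction-probability iteration did not converge")


def large_tree_probability(d: OffspringDistribution) -> float:
    """Survival probability ``1 - q``.

    The infinite-size limit of the probability that a tree reaches a
    size cap N; it upper-bounds the simulated large-tree proportion at
    any finite N (a surviving tree always reaches the cap, while a
    tree can reach a finite cap and still be destined for extinction
    only with the small complementary probability).
    """
    return 1.0 - extinction_probability(d)


def critical_boundary(sigma2: float, p: float, c: int) -> float | None:
    """Critical mean number of sent invitations for given acceptance.

    Recruitment is sustainable once the mean number of *successful*
    invitations ``mu * p`` exceeds 1, so the critical sent-mean is
    ``mu* = 1 / p`` — independent of the variance, which only shapes
    how fast the survival probability rises beyond the threshold.
    Returns ``None`` ("unreachable") when ``1 / p > c``: even senders
    maxing out their coupons cannot cross the threshold.
    """
    if p <= 0.0 or p > 1.0:
        raise ParameterError(f"need acceptance probability in (0, 1], got {p}")
    if sigma2 < 0:
        raise ParameterError("variance must be non-negative")
    mu_star = 1.0 / p
    return None if mu_star > c else mu_star


def markov_composition(
    initial,
    transition,
    waves: int,
) -> np.ndarray:
    """Expected per-wave category distribution of the sample.

    Because recruitee categories depend only on the direct recruiter,
    the expected wave-W composition follows a Markov chain: row vector
    ``pi_{W+1} = pi_W @ T``.  ``transition`` is either one
    row-stochastic matrix or a mapping ``{band: matrix}`` over wave
    bands ``{0, 1, 2}`` (band 2 reused for waves >= 2), mirroring
    wave-stratified mixing.  Returns an array of shape
    ``(waves + 1, k)`` whose first row is ``initial``.
    """
    pi = np.asarray(initial, dtype=float)
    if pi.ndim != 1 or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ParameterError("initial composition must be a probability vector")

    def matrix_for(wave: int) -> np.ndarray:
        t = transition[min(wave, 2)] if isinstance(transition, dict) else transition
        t = np.asarray(t, dtype=float)
        if t.shape != (pi.size, pi.size):
            raise ConfigurationError("transition matrix shape mismatch")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("transition rows must sum to 1")
        return t

    out = np.empty((waves + 1, pi.size))
    out[0] = pi
    for w in range(waves):
        pi = pi @ matrix_for(w)
        out[w + 1] = pi
    return out


def mean_offspring_matrix(type_table, mixing: MixingModel) -> np.ndarray:
    """Mean matrix of the multi-type branching process.

    ``M[i, j]`` is the expected number of type-``j`` recruitees
    produced by one type-``i`` recruiter: the type's mean number of
    accepted invitations times the probability (product over the three
    independent characteristics) that a recruitee of a type-``i``
    recruiter is of type ``j``.  Uses the recruitee stratum of the
    type table and the overall (band 0) mixing tables.
    """
    k = len(RECRUITER_TYPES)
    m = np.zeros((k, k))
    cats = {c: list(v) for c, v in CHARACTERISTICS.items()}
    for i, ti in enumerate(RECRUITER_TYPES):
        tp = type_table.params_for(".".join(ti))
        mom = tp.invitations.moments()
        mean_acc = mom.mu * tp.acceptance
        for j, tj in enumerate(RECRUITER_TYPES):
            prob = 1.0
            for char, (ci, cj) in zip(CHARACTERISTICS, zip(ti, tj)):
                row = mixing.row(char, ci, 0)
                prob *= row[cats[char].index(cj)]
            m[i, j] = mean_acc * prob
    return m


def spectral_radius(matrix: np.ndarray) -> float:
    """Largest eigenvalue magnitude; the multi-type process is
    supercritical exactly when this exceeds 1."""
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(matrix, dtype=float)))))
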