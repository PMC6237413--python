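"""Invitation-count distributions.

The number of coupons a recruiter actually sends is modelled as a
beta-binomial random variable on ``{0, ..., c}``: a binomial count whose
per-coupon sending probability is itself beta distributed with shapes
``alpha`` and ``beta``.  The beta-binomial covers the full range of
behaviour seen in respondent-driven surveys, from near-binomial
unimodal sending up to strongly bimodal behaviour where most
participants send nothing and a minority sends the maximum number of
coupons.  Acceptance of a sent invitation is an independent Bernoulli
event per coupon, so the number of *accepted* invitations is a binomial
thinning of the sent count.

Scenario tables usually speak in terms of the mean ``mu`` and variance
``sigma2`` of the sent count; the model itself is defined via the
shapes.  This module provides both parameterisations and the conversion
between them, the feasible variance band for a given mean, degenerate
point-mass limits, and maximum-likelihood fitting of the shapes from
observed counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from ._exceptions import (
    DegenerateDistributionError,
    FeasibilityError,
    ParameterError,
)

__all__ = [
    "BetaBinomialParams",
    "MomentSpec",
    "PointMass",
    "bb_pmf",
    "bb_sample",
    "bb_moments",
    "bb_from_moments",
    "variance_bounds",
    "point_mass",
    "thin",
    "bb_fit_mle",
    "BetaBinomialFit",
]


@dataclass(frozen=True)
class MomentSpec:
    """Mean and variance of an invitation-count distribution."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ParameterError(f"variance must be non-negative, got {self.sigma2}")


@dataclass(frozen=True)
class BetaBinomialParams:
    """Shape parameters of a beta-binomial distribution on ``{0..c}``.

    Parameters
    ----------
    alpha, beta
        Positive shape parameters of the mixing beta distribution.
    c
        Maximum number of coupons a recruiter can send (inclusive).
    """

    alpha: float
    beta: float
    c: int = 4

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ParameterError(f"alpha must be positive and finite, got {self.alpha}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ParameterError(f"beta must be positive and finite, got {self.beta}")
        if int(self.c) != self.c or self.c < 1:
            raise ParameterError(f"c must be an integer >= 1, got {self.c}")

    # -- distribution protocol (shared with PointMass) ------------------
    def pmf(self, k: int | np.ndarray) -> float | np.ndarray:
        return bb_pmf(k, self)

    def pmf_vector(self) -> np.ndarray:
        """Probabilities of 0..c as a length ``c+1`` array."""
        return bb_pmf(np.arange(self.c + 1), self)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return bb_sample(self, n, rng)

    def moments(self) -> MomentSpec:
        return bb_moments(self)


@dataclass(frozen=True)
class PointMass:
    """Degenerate invitation distribution: every recruiter sends exactly
    ``k`` invitations.

    Stands in for the limits ``mu = 0``, ``mu = c`` or ``sigma2 = 0``
    which are not representable by finite beta-binomial shapes, and is
    accepted anywhere a :class:`BetaBinomialParams` is.
    """

    k: int
    c: int = 4

    def __post_init__(self) -> None:
        if int(self.k) != self.k or int(self.c) != self.c:
            raise ParameterError("k and c must be integers")
        if not (0 <= self.k <= self.c):
            raise ParameterError(f"need 0 <= k <= c, got k={self.k}, c={self.c}")

    def pmf(self, k: int | np.ndarray) -> float | np.ndarray:
        k = np.asarray(k)
        if np.any((k < 0) | (k > self.c)):
            raise ParameterError(f"k outside support {{0..{self.c}}}")
        out = np.where(k == self.k, 1.0, 0.0)
        return float(out) if out.ndim == 0 else out

    def pmf_vector(self) -> np.ndarray:
        v = np.zeros(self.c + 1)
        v[self.k] = 1.0
        return v

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 0:
            raise ParameterError("sample size must be >= 0")
        return np.full(n, self.k, dtype=np.int64)

    def moments(self) -> MomentSpec:
        return MomentSpec(mu=float(self.k), sigma2=0.0)


def point_mass(k: int, c: int = 4) -> PointMass:
    """Distribution that sends exactly ``k`` of at most ``c`` coupons."""
    return PointMass(k=k, c=c)


def bb_pmf(k: int | np.ndarray, params: BetaBinomialParams) -> float | np.ndarray:
    """Beta-binomial probability mass ``P(X = k)``.

    For the usual small coupon counts the pmf is built by the stable
    ratio recurrence ``pmf(k+1)/pmf(k) = (c-k)(alpha+k) /
    ((k+1)(beta+c-k-1))`` started from ``pmf(0) = prod_j
    (beta+j)/(alpha+beta+j)``, whose factors are exact to machine
    precision even for the extreme shapes of strongly bimodal
    distributions (alpha, beta << 1).  Large supports fall back to the
    log-beta-function formula to avoid overflow in the products.
    """
    k_arr = np.asarray(k)
    if np.any((k_arr < 0) | (k_arr > params.c)):
        raise ParameterError(f"k outside support {{0..{params.c}}}")
    a, b, c = params.alpha, params.beta, params.c
    if c <= 64:
        pmf = np.empty(c + 1)
        j = np.arange(c)
        pmf[0] = np.prod((b + j) / (a + b + j))
        for i in range(c):
            pmf[i + 1] = pmf[i] * ((c - i) * (a + i)) / ((i + 1) * (b + c - i - 1))
        out = pmf[k_arr]
    else:
        logpmf = (
            special.gammaln(c + 1)
            - special.gammaln(k_arr + 1)
            - special.gammaln(c - k_arr + 1)
            + special.betaln(k_arr + a, c - k_arr + b)
            - special.betaln(a, b)
        )
        out = np.exp(logpmf)
    return float(out) if out.ndim == 0 else out


def bb_sample(params: BetaBinomialParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. beta-binomial invitation counts.

    Uses the defining mixture: a beta draw of the per-coupon sending
    probability followed by a binomial draw of the count.
    """
    if n < 0:
        raise ParameterError("sample size must be >= 0")
    if n == 0:
        return np.empty(0, dtype=np.int64)
    probs = rng.beta(params.alpha, params.beta, size=n)
    return rng.binomial(params.c, probs)


def bb_moments(params: BetaBinomialParams | PointMass) -> MomentSpec:
    """Mean and variance implied by beta-binomial shapes.

    ``mu = c*pi`` and ``sigma2 = c*pi*(1-pi)*(1 + (c-1)*rho)`` with
    ``pi = alpha/(alpha+beta)`` the mean per-coupon probability and
    ``rho = 1/(alpha+beta+1)`` the within-recruiter overdispersion.
    """
    if isinstance(params, PointMass):
        return params.moments()
    a, b, c = params.alpha, params.beta, params.c
    pi = a / (a + b)
    rho = 1.0 / (a + b + 1.0)
    mu = c * pi
    sigma2 = c * pi * (1.0 - pi) * (1.0 + (c - 1.0) * rho)
    return MomentSpec(mu=mu, sigma2=sigma2)


def variance_bounds(mu: float, c: int) -> tuple[float, float]:
    """Open band of variances a beta-binomial with mean ``mu`` can attain.

    The lower bound ``mu*(1 - mu/c)`` is the binomial limit
    (``alpha + beta -> inf``); the upper bound ``mu*(c - mu)`` is the
    two-point limit concentrated on ``{0, c}`` (``alpha + beta -> 0``).
    Both bounds are open: finite shapes give variances strictly inside.
    """
    if not (0 <= mu <= c):
        raise ParameterError(f"mean must lie in [0, {c}], got {mu}")
    lo = mu * (1.0 - mu / c)
    hi = mu * (c - mu)
    return lo, hi


def bb_from_moments(
    spec: MomentSpec,
    c: int = 4,
    *,
    clamp: bool = False,
) -> BetaBinomialParams:
    """Invert the moment identities to beta-binomial shapes.

    Closed form: with ``pi = mu/c`` and the binomial-floor variance
    ``v0 = c*pi*(1-pi)``, the overdispersion is
    ``rho = (sigma2/v0 - 1)/(c - 1)`` and ``alpha + beta = 1/rho - 1``.

    Parameters
    ----------
    spec
        Target mean and variance; the mean must be strictly inside
        ``(0, c)`` and the variance strictly inside
        :func:`variance_bounds` unless ``clamp`` is set.
    clamp
        Project an out-of-band variance onto the nearest point 1e-6
        inside the open band instead of raising.  Mirrors the common
        practice of replacing an incompatible sample variance by the
        closest representable one.
    """
    if int(c) != c or c < 2:
        raise ParameterError(f"moment inversion needs integer c >= 2, got {c}")
    mu, sigma2 = float(spec.mu), float(spec.sigma2)
    if not (0 <= mu <= c):
        raise ParameterError(f"mean must lie in [0, {c}], got {mu}")
    if mu == 0.0 or mu == c:
        raise DegenerateDistributionError(
            f"mu={mu} forces a point mass at {int(mu)}; use point_mass({int(mu)}, c={c})"
        )
    lo, hi = variance_bounds(mu, c)
    if not (lo < sigma2 < hi):
        if clamp:
            sigma2 = min(max(sigma2, lo + 1e-6), hi - 1e-6)
        elif sigma2 == 0.0:
            raise DegenerateDistributionError(
                f"sigma2=0 is a point mass; representable only for integer mu"
            )
        else:
            raise FeasibilityError(
                f"sigma2={sigma2} infeasible for mu={mu}, c={c}: the admissible "
                f"band is the open interval ({lo:.6g}, {hi:.6g})"
            )
    pi = mu / c
    rho = (sigma2 / (c * pi * (1.0 - pi)) - 1.0) / (c - 1.0)
    s = 1.0 / rho - 1.0  # alpha + beta
    return BetaBinomialParams(alpha=pi * s, beta=(1.0 - pi) * s, c=c)


def thin(
    n_sent: int | np.ndarray,
    p: float,
    rng: np.random.Generator,
) -> int | np.ndarray:
    """Number of accepted invitations out of ``n_sent``.

    Each sent invitation is accepted independently with probability
    ``p``, i.e. a ``Binomial(n_sent, p)`` draw.
    """
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"acceptance probability must be in [0, 1], got {p}")
    n_arr = np.asarray(n_sent)
    if np.any(n_arr < 0):
        raise ParameterError("sent counts must be >= 0")
    out = rng.binomial(n_arr, p)
    return int(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class BetaBinomialFit:
    """Result of a beta-binomial maximum-likelihood fit."""

    params: BetaBinomialParams
    log_likelihood: float
    converged: bool
    n_obs: int

    @property
    def moments(self) -> MomentSpec:
        return bb_moments(self.params)


def bb_fit_mle(counts, c: int = 4) -> BetaBinomialFit:
    """Maximum-likelihood beta-binomial shapes from observed counts.

    Optimises the log-likelihood over log-shapes with a bounded
    quasi-Newton method (L-BFGS-B), started from the moment-matching
    estimate (or from alpha=beta=1 if the sample variance falls outside
    the representable band).  The log parameterisation keeps the shapes
    positive and makes the fit deterministic given the data.

    Raises
    ------
    DegenerateDistributionError
        If all counts are equal (the MLE diverges to a point mass).
    """
    x = np.asarray(counts, dtype=np.int64)
    if x.size == 0:
        raise ParameterError("need at least one observed count")
    if np.any((x < 0) | (x > c)):
        raise ParameterError(f"counts must lie in {{0..{c}}}")
    if np.all(x == x[0]):
        raise DegenerateDistributionError(
            f"all counts equal {x[0]}: the MLE is the point mass point_mass({x[0]}, c={c})"
        )

    # sufficient statistics: frequency of each count value
    freqs = np.bincount(x, minlength=c + 1).astype(float)
    ks = np.arange(c + 1)
    log_binom = (
        special.gammaln(c + 1) - special.gammaln(ks + 1) - special.gammaln(c - ks + 1)
    )

    def negloglik(log_shapes: np.ndarray) -> float:
        a, b = np.exp(log_shapes)
        ll = freqs @ (
            log_binom + special.betaln(ks + a, c - ks + b) - special.betaln(a, b)
        )
        return -ll

    mu, s2 = float(x.mean()), float(x.var(ddof=0))
    try:
        start = bb_from_moments(MomentSpec(mu, s2), c)
        x0 = np.log([start.alpha, start.beta])
    except ParameterError:
        x0 = np.zeros(2)  # alpha = beta = 1

    res = optimize.minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        bounds=[(math.log(1e-8), math.log(1e8))] * 2,
    )
    if not res.success:
        raise RuntimeError(f"beta-binomial MLE did not converge: {res.message}")
    a_hat, b_hat = np.exp(res.x)
    return BetaBinomialFit(
        params=BetaBinomialParams(alpha=float(a_hat), beta=float(b_hat), c=c),
        log_likelihood=float(-res.fun),
        converged=bool(res.success),
        n_obs=int(x.size),
    )
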