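"""Exact probability kernels for binomial sequential monitoring.

Everything downstream (the satisfaction statistic, boundary searches, exact
operating characteristics) reduces to three ingredients: the binomial
sampling distribution of the responder count, the conjugate beta posterior
on the response probability, and the beta-binomial posterior predictive for
the responders still to be observed.  This module wraps those kernels with
validated domain types.  All heavy lifting is delegated to ``scipy.stats``,
which evaluates these distributions through log-gamma arithmetic and so
stays accurate far into the tails (interim tail probabilities here range
from ~1e-3 down past 1e-12) and accepts non-integer beta hyper-parameters
such as the elicited 49.5 or 69.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BetaPrior",
    "InterimData",
    "binom_pmf",
    "binom_cdf",
    "binom_sf",
    "betabinom_pmf",
    "posterior_update",
]


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior on the response probability.

    ``a`` acts as prior pseudo-successes and ``b`` as prior pseudo-failures;
    ``a + b`` measures the weight of prior information in patients.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"beta hyper-parameters must be positive, got a={self.a}, b={self.b}")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class InterimData:
    """Cumulative trial state at a look: ``n`` patients observed, ``z`` responders."""

    n: int
    z: int

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and isinstance(self.z, (int, np.integer))):
            raise TypeError("interim counts must be integers")
        if not (0 <= self.z <= self.n):
            raise ValueError(f"need 0 <= z <= n, got z={self.z}, n={self.n}")


def _check_p(p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must lie in [0, 1], got {p}")


def binom_pmf(k: int, n: int, p: float):
    """P(Z = k) for Z ~ Binomial(n, p).  Vectorized over ``k``."""
    _check_p(p)
    if n < 0:
        raise ValueError("n must be nonnegative")
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr > n):
        raise ValueError(f"k must lie in 0..{n}")
    out = stats.binom.pmf(k_arr, n, p)
    return float(out) if np.isscalar(k) else out

def binom_cdf(k: int, n: int, p: float) -> float:
    """P(Z <= k); k below 0 gives 0, k above n gives 1."""
    _check_p(p)
    return float(stats.binom.cdf(k, n, p))


def binom_sf(k: int, n: int, p: float) -> float:
    """Upper tail P(Z >= k), the complement of ``binom_cdf(k - 1)``.

    Computed by scipy's survival function (a direct tail evaluation, not a
    1 - cdf subtraction), so small efficacy tails keep full precision.
    """
    _check_p(p)
    return float(stats.binom.sf(k - 1, n, p))


def posterior_update(prior: BetaPrior, data: InterimData) -> BetaPrior:
    """Conjugate update: Beta(a, b) + (n, z) -> Beta(a + z, b + n - z).

    Sequential application over split cohorts equals a single pooled update,
    which is what makes multi-look monitoring coherent.
    """
    return BetaPrior(prior.a + data.z, prior.b + data.n - data.z)


def betabinom_pmf(y, m: int, post: BetaPrior):
    """Posterior predictive P(Y = y) for the responders among ``m`` future patients.

    Y ~ BetaBinomial(m, post.a, post.b): the binomial likelihood averaged over
    the beta posterior on the response probability.  Vectorized over ``y``.
    """
    if m < 0:
        raise ValueError("m must be nonnegative")
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or np.any(y_arr > m):
        raise ValueError(f"y must lie in 0..{m}")
    out = stats.betabinom.pmf(y_arr, m, post.a, post.b)
    return float(out) if np.isscalar(y) else out
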