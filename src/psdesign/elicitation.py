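"""Design-prior elicitation from a mean response rate and a coefficient of variation.

An investigator states an anticipated response rate ``mean`` and a coefficient
of variation ``cv`` expressing confidence in it (10% high, 25% moderate, 50%
low confidence).  Matching the beta distribution's first two moments gives

    a = (1 - mean) / cv**2 - mean,        b = a * (1/mean - 1),

so that Beta(a, b) has exactly the stated mean and sd/mean ratio.  Large cv
at a given mean eventually drives ``a`` (or ``b``) nonpositive, i.e. no beta
distribution carries that little information at that mean; such requests are
rejected with the maximal admissible cv named.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .distributions import BetaPrior

__all__ = ["ElicitationInput", "ElicitationError", "elicit_beta", "flat_prior", "describe_prior"]


@dataclass(frozen=True)
class ElicitationInput:
    mean: float  # anticipated response rate, in (0, 1)
    cv: float    # coefficient of variation sd/mean, as a fraction (0.10 = 10%)

    def __post_init__(self) -> None:
        if not (0.0 < self.mean < 1.0):
            raise ValueError(f"mean must lie in (0, 1), got {self.mean}")
        if not self.cv > 0:
            raise ValueError(f"cv must be positive, got {self.cv}")


class ElicitationError(ValueError):
    """The stated (mean, cv) pair admits no proper beta prior."""


def max_admissible_cv(mean: float) -> float:
    """Largest cv for which the moment-matched ``a`` stays positive at this mean."""
    return math.sqrt((1.0 - mean) / mean) * (1.0 + 1e-12) ** -1


def elicit_beta(inp: ElicitationInput) -> BetaPrior:
    """Moment-match a Beta(a, b) prior to the elicited mean and cv."""
    a = (1.0 - inp.mean) / inp.cv**2 - inp.mean
    if a <= 0:
        raise ElicitationError(
            f"cv={inp.cv} is too large for mean={inp.mean}: no beta prior has that "
            f"coefficient of variation (maximal admissible cv ~= {max_admissible_cv(inp.mean):.4f})"
        )
    b = a * (1.0 / inp.mean - 1.0)
    return BetaPrior(a, b)


def flat_prior() -> BetaPrior:
    """The non-informative Beta(1, 1) (uniform) prior."""
    return BetaPrior(1.0, 1.0)


def describe_prior(prior: BetaPrior) -> dict:
    """Moments and central 95% credible interval of a beta prior."""
    a, b = prior.a, prior.b
    mean = a / (a + b)
    cv = math.sqrt(b / (a * (a + b + 1.0)))
    lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
    return {"a": a, "b": b, "mean": mean, "cv": cv, "ci95": (float(lo), float(hi))}
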