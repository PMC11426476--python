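"""The satisfaction index and its interim prediction.

The trial tests H0: theta <= theta0 against H1: theta > theta0 on the total
responder count Z out of ``n_max`` patients.  At the final analysis the
treatment is declared efficient when Z reaches an efficacy threshold chosen
so that the exact binomial type I error does not exceed alpha.  The
*satisfaction index* phi(z) is 0 outside the rejection region and otherwise
1 minus the final p-value — an increasing measure of how convincing the
final result is.

At an interim look with z responders among n patients, the *prediction of
satisfaction* pi(z) averages a satisfaction weight over the beta-binomial
posterior predictive distribution of the responders Y still to come among
the m* = n_max - n remaining patients, restricted to futures that reach the
efficacy threshold:

    pi(z) = sum_{y = (t_eff - z)+ .. m*}  w(y) * P(Y = y | z, n)

with w(y) the binomial(m*, theta0) cdf at y.  pi lies in [0, 1], increases
in z, and is the monitoring statistic: the trial stops for futility when pi
falls below a threshold gamma.

Two dialect switches are exposed because the source conventions admit two
off-by-one readings.  The ``calibrated`` dialect (default) uses the strict
upper tail for the efficacy threshold and cdf upper limit y; it is the one
that reproduces all published worked values.  The ``literal`` dialect keeps
the weak-tail threshold and cdf upper limit y - 1 as printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import BetaPrior, InterimData, posterior_update
from .elicitation import flat_prior

__all__ = [
    "Dialect",
    "TrialDesign",
    "EfficacyThreshold",
    "efficacy_threshold",
    "satisfaction_index",
    "prediction_of_satisfaction",
    "ps_table",
]

Dialect = Literal["calibrated", "literal"]


@dataclass(frozen=True)
class EfficacyThreshold:
    """Minimum total responders at n_max at which efficacy is declared."""

    t_eff: int


@dataclass(frozen=True)
class TrialDesign:
    """Parameters of a PS futility-monitoring design.

    ``looks`` are cumulative sample sizes at the analyses, the last being the
    final analysis at ``n_max``.  ``gamma`` is the futility threshold on the
    prediction of satisfaction: continue only while pi >= gamma.
    """

    theta0: float
    theta1: float
    alpha: float
    power_target: float
    gamma: float
    n_max: int
    looks: tuple[int, ...]
    prior: BetaPrior = field(default_factory=flat_prior)
    dialect: Dialect = "calibrated"

    def __post_init__(self) -> None:
        if not (0.0 < self.theta0 < self.theta1 < 1.0):
            raise ValueError(f"need 0 < theta0 < theta1 < 1, got {self.theta0}, {self.theta1}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 <= self.power_target < 1.0):
            raise ValueError(f"power_target must lie in [0, 1), got {self.power_target}")
        if not (0.5 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must lie in [0.5, 1], got {self.gamma}")
        looks = tuple(self.looks)
        object.__setattr__(self, "looks", looks)
        if any(b <= a for a, b in zip(looks, looks[1:])):
            raise ValueError(f"looks must be strictly increasing, got {looks}")
        if not looks or looks[-1] != self.n_max:
            raise ValueError(f"last look must equal n_max={self.n_max}, got {looks}")
        if self.dialect not in ("calibrated", "literal"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    @property
    def interim_looks(self) -> tuple[int, ...]:
        return self.looks[:-1]


def efficacy_threshold(
    n_max: int, theta0: float, alpha: float, dialect: Dialect = "calibrated"
) -> EfficacyThreshold:
    """Smallest responder total whose null tail probability is within alpha.

    calibrated: min{u : P(Z > u | theta0) <= alpha}; literal uses the weak
    tail P(Z >= u).  The calibrated reading gives thresholds 20 and 19 for
    n_max=50, theta0=0.3 at alpha 0.05 and 0.10 — the values the published
    worked designs actually use.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not (0.0 <= theta0 <= 1.0):
        raise ValueError(f"theta0 must lie in [0, 1], got {theta0}")
    u = np.arange(n_max + 1)
    if dialect == "calibrated":
        tails = stats.binom.sf(u, n_max, theta0)  # P(Z > u)
    else:
        tails = stats.binom.sf(u - 1, n_max, theta0)  # P(Z >= u)
    ok = np.nonzero(tails <= alpha)[0]
    if ok.size == 0:  # cannot happen for u = n_max unless theta0 = 1 and literal
        return EfficacyThreshold(n_max + 1)
    return EfficacyThreshold(int(ok[0]))


def satisfaction_index(z: int, n_max: int, theta0: float, t: EfficacyThreshold) -> float:
    """phi(z): 0 outside the rejection region, else 1 minus the final p-value."""
    if not (0 <= z <= n_max):
        raise ValueError(f"z must lie in 0..{n_max}, got {z}")
    if z < t.t_eff:
        return 0.0
    # 1 - P(Z >= z | theta0) = P(Z <= z - 1)
    return float(stats.binom.cdf(z - 1, n_max, theta0))


def prediction_of_satisfaction(data: InterimData, design: TrialDesign) -> float:
    """pi(z): predictive average of the satisfaction weight over efficacious futures.

    Defined for any interim n < n_max (the formula does not involve the look
    schedule).  Nondecreasing in z at fixed n; equals ~1 when efficacy is
    already near-certain and 0 when the threshold is out of reach.
    """
    if data.n >= design.n_max:
        raise ValueError(
            f"n={data.n} is not interim for n_max={design.n_max}; "
            "the trial is complete — use satisfaction_index"
        )
    t = efficacy_threshold(design.n_max, design.theta0, design.alpha, design.dialect)
    m = design.n_max - data.n
    lo = max(t.t_eff - data.z, 0)
    if lo > m:
        return 0.0  # efficacy unreachable: empty sum
    post = posterior_update(design.prior, data)
    y = np.arange(lo, m + 1)
    upper = y if design.dialect == "calibrated" else y - 1
    w = stats.binom.cdf(upper, m, design.theta0)
    mass = stats.betabinom.pmf(y, m, post.a, post.b)
    return float(np.dot(w, mass))


def ps_table(
    design: TrialDesign,
    n_interim: int,
    scenarios: Sequence[tuple[str, BetaPrior, int]] | None = None,
) -> pd.DataFrame:
    """Prediction of satisfaction for every z = 0..n_interim at one look.

    By default a single column for the design's own prior and n_max; pass
    ``scenarios`` as (label, prior, n_max) triples to tabulate several
    prior / maximum-sample-size combinations side by side.
    """
    if n_interim >= design.n_max:
        raise ValueError(f"n_interim must be < n_max={design.n_max}")
    if scenarios is None:
        scenarios = [(f"Nmax={design.n_max}", design.prior, design.n_max)]
    out: dict[str, list[float]] = {}
    for label, prior, n_max in scenarios:
        d = TrialDesign(
            theta0=design.theta0,
            theta1=design.theta1,
            alpha=design.alpha,
            power_target=design.power_target,
            gamma=design.gamma,
            n_max=n_max,
            looks=(n_interim, n_max),
            prior=prior,
            dialect=design.dialect,
        )
        out[label] = [
            prediction_of_satisfaction(InterimData(n=n_interim, z=z), d)
            for z in range(n_interim + 1)
        ]
    return pd.DataFrame(out, index=pd.RangeIndex(n_interim + 1, name="z"))
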