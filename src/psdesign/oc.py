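"""Exact frequentist operating characteristics of multi-look futility designs.

A design is summarized by a :class:`StoppingRule`: one continuation boundary
c_k per interim look (stop for futility iff the cumulative responder count is
strictly below c_k) plus the final efficacy threshold t_eff.  For any true
response rate theta the exact rejection probability, per-stage stopping
probabilities, probability of early termination (PET) and expected sample
size follow from forward dynamic programming over the cumulative responder
count: the state distribution is propagated look to look by binomial
increments, the sub-boundary mass is removed at each look, and the surviving
mass at n_max is scored against t_eff.

The classical closed-form sums for two- and three-stage designs are kept in
:func:`oc_closed_form` as an independent cross-check of the DP; the DP is
normative for any number of looks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .satisfaction import EfficacyThreshold, TrialDesign

__all__ = ["StoppingRule", "OCResult", "oc_exact", "oc_closed_form", "oc_summary"]


@dataclass(frozen=True)
class StoppingRule:
    """Continuation boundaries per interim look plus the final efficacy threshold.

    At interim look k the trial continues iff cumulative responders >= boundaries[k].
    A boundary equal to (look size + 1) would stop with certainty and marks an
    invalid design.
    """

    boundaries: tuple[int, ...]
    t_eff: EfficacyThreshold

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundaries", tuple(int(c) for c in self.boundaries))
        if any(c < 0 for c in self.boundaries):
            raise ValueError(f"boundaries must be nonnegative, got {self.boundaries}")


@dataclass(frozen=True)
class OCResult:
    """Exact operating characteristics at one true response rate."""

    theta: float
    reject_prob: float
    pet: float
    stop_by_stage: tuple[float, ...]
    expected_n: float


def _validate(rule: StoppingRule, looks: Sequence[int], n_max: int) -> tuple[int, ...]:
    looks = tuple(int(n) for n in looks)
    if any(b <= a for a, b in zip(looks, looks[1:])):
        raise ValueError(f"looks must be strictly increasing, got {looks}")
    if looks and looks[-1] >= n_max:
        raise ValueError(f"interim looks must precede n_max={n_max}, got {looks}")
    if len(rule.boundaries) != len(looks):
        raise ValueError(
            f"{len(looks)} interim looks but {len(rule.boundaries)} boundaries"
        )
    for c, n in zip(rule.boundaries, looks):
        if c > n + 1:
            raise ValueError(f"boundary {c} exceeds look size {n} + 1")
    return looks


def oc_exact(rule: StoppingRule, looks: Sequence[int], n_max: int, theta: float) -> OCResult:
    """Exact OC by forward DP over cumulative responder counts.

    ``looks`` lists the cumulative sample sizes of the interim analyses only;
    the final analysis happens at ``n_max``.
    """
    looks = _validate(rule, looks, n_max)
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must lie in [0, 1], got {theta}")

    dist = np.ones(1)  # P(cumulative responders = offset + i)
    offset = 0
    prev = 0
    stop_by_stage: list[float] = []
    for c, n in zip(rule.boundaries, looks):
        inc = n - prev
        step = stats.binom.pmf(np.arange(inc + 1), inc, theta)
        dist = np.convolve(dist, step)
        cut = max(c - offset, 0)  # states with z < c stop for futility
        stop_by_stage.append(float(dist[:cut].sum()))
        dist = dist[cut:].copy()
        offset += cut
        prev = n
        if dist.size == 0:
            break
    # final stage: surviving states need total >= t_eff
    reject = 0.0
    if dist.size:
        inc = n_max - prev
        z_now = offset + np.arange(dist.size)
        need = rule.t_eff.t_eff - z_now
        tail = stats.binom.sf(need - 1, inc, theta)  # P(future >= need)
        reject = float(np.dot(dist, tail))
    while len(stop_by_stage) < len(looks):
        stop_by_stage.append(0.0)
    pet = float(sum(stop_by_stage))
    expected_n = float(
        sum(n * s for n, s in zip(looks, stop_by_stage)) + n_max * (1.0 - pet)
    )
    return OCResult(
        theta=theta,
        reject_prob=reject,
        pet=pet,
        stop_by_stage=tuple(stop_by_stage),
        expected_n=expected_n,
    )


def oc_closed_form(
    rule: StoppingRule, looks: Sequence[int], n_max: int, theta: float
) -> OCResult:
    """Two- and three-stage OC by the explicit binomial sums.

    Independent of the DP path: nested sums over per-stage responder counts
    with the stop-iff-below-boundary convention.  Raises for more than two
    interim looks (the DP is normative there).
    """
    looks = _validate(rule, looks, n_max)
    k = len(looks)
    if k not in (1, 2):
        raise ValueError("closed forms cover 2- and 3-stage designs only; use oc_exact")
    b = stats.binom
    q = rule.t_eff.t_eff
    if k == 1:
        (c1,), (n1,) = rule.boundaries, looks
        n2 = n_max - n1
        i = np.arange(c1, n1 + 1)
        reject = float(np.dot(b.pmf(i, n1, theta), b.sf(q - 1 - i, n2, theta)))
        stop1 = float(b.cdf(c1 - 1, n1, theta))
        stop = (stop1,)
    else:
        (c1, c2), (n1, n2c) = rule.boundaries, looks
        n2 = n2c - n1
        n3 = n_max - n2c
        i = np.arange(c1, n1 + 1)
        p1 = b.pmf(i, n1, theta)
        stop1 = float(b.cdf(c1 - 1, n1, theta))
        # stop at look 2: i + j < c2
        stop2 = float(np.dot(p1, b.cdf(c2 - 1 - i, n2, theta)))
        # reach final with i + j >= c2, then need >= q - i - j more
        reject = 0.0
        for ii, pii in zip(i, p1):
            j = np.arange(max(c2 - ii, 0), n2 + 1)
            reject += pii * float(
                np.dot(b.pmf(j, n2, theta), b.sf(q - 1 - ii - j, n3, theta))
            )
        stop = (stop1, stop2)
    pet = float(sum(stop))
    expected_n = float(sum(n * s for n, s in zip(looks, stop)) + n_max * (1.0 - pet))
    return OCResult(theta, float(reject), pet, stop, expected_n)


def oc_summary(design: TrialDesign, rule: StoppingRule) -> dict:
    """Design report: type I error, power, PET and E(N) under both hypotheses."""
    looks = design.interim_looks
    at0 = oc_exact(rule, looks, design.n_max, design.theta0)
    at1 = oc_exact(rule, looks, design.n_max, design.theta1)
    return {
        "boundaries": rule.boundaries,
        "t_eff": rule.t_eff.t_eff,
        "looks": tuple(looks) + (design.n_max,),
        "type_i_error": at0.reject_prob,
        "power": at1.reject_prob,
        "pet_null": at0.pet,
        "pet_alt": at1.pet,
        "expected_n_null": at0.expected_n,
        "expected_n_alt": at1.expected_n,
    }
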