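"""From statistic to design: boundary construction and sample-size search.

Per-look futility boundaries come from the PS rule — the smallest responder
count whose prediction of satisfaction reaches gamma — bumped up by the
smallest amount needed to keep the design's *exact* type I error within
alpha (the PS rule alone can admit a slightly anticonservative boundary; the
published two-stage design at alpha=0.05 is exactly such a case, where the
smallest PS-qualifying count 10 yields exact size ~0.060 and the operative
boundary is 11).

The maximum sample size is searched around a normal-approximation seed

    N0 = ceil( theta~ (1 - theta~) [ (u_{1-alpha} + u_{1-beta}) / (theta1 - theta0) ]^2 ),
    theta~ = (theta0 + theta1) / 2,

downward to the least feasible N_max and then upward until the optimality
criterion has clearly stopped improving.  ``minimax`` minimizes N_max;
``optimal`` minimizes the expected sample size under the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy.stats import norm

from .distributions import BetaPrior, InterimData
from .elicitation import flat_prior
from .oc import OCResult, StoppingRule, oc_exact, oc_summary
from .satisfaction import (
    Dialect,
    TrialDesign,
    efficacy_threshold,
    prediction_of_satisfaction,
)

__all__ = [
    "InfeasibleDesignError",
    "DesignResult",
    "initial_sample_size",
    "stage_boundary",
    "build_rule",
    "find_design",
]


class InfeasibleDesignError(RuntimeError):
    """No boundary/design satisfies the stated constraints."""


@dataclass(frozen=True)
class DesignResult:
    design: TrialDesign
    rule: StoppingRule
    oc: dict  # oc_summary row

    @property
    def n_max(self) -> int:
        return self.design.n_max


def initial_sample_size(
    theta0: float, theta1: float, alpha: float, power_target: float
) -> int:
    """Single-stage normal-approximation sample size, the N_max scan seed."""
    if not theta0 < theta1:
        raise ValueError(f"need theta0 < theta1, got {theta0}, {theta1}")
    if not (0.0 < power_target < 1.0):
        raise ValueError(f"power_target must lie in (0, 1), got {power_target}")
    theta_bar = 0.5 * (theta0 + theta1)
    u = norm.ppf(1.0 - alpha) + norm.ppf(power_target)
    return int(math.ceil(theta_bar * (1.0 - theta_bar) * (u / (theta1 - theta0)) ** 2))


def stage_boundary(
    design: TrialDesign, look_n: int, rule_so_far: StoppingRule | None = None
) -> int:
    """Continuation boundary at one look: PS rule, then exact-alpha bump.

    Returns the smallest c such that pi(c) >= gamma at ``look_n`` *and* the
    design consisting of all previously fixed boundaries plus c at this look
    (and the final efficacy threshold) has exact type I error <= alpha.
    """
    if look_n >= design.n_max:
        raise ValueError(f"look_n={look_n} must be interim (< n_max={design.n_max})")
    prev_bounds: tuple[int, ...] = rule_so_far.boundaries if rule_so_far else ()
    prev_looks = tuple(n for n in design.interim_looks if n < look_n)
    if len(prev_looks) != len(prev_bounds):
        raise ValueError(
            f"rule_so_far has {len(prev_bounds)} boundaries but the design schedules "
            f"{len(prev_looks)} earlier looks"
        )
    t = efficacy_threshold(design.n_max, design.theta0, design.alpha, design.dialect)
    c = None
    for z in range(look_n + 1):
        if prediction_of_satisfaction(InterimData(n=look_n, z=z), design) >= design.gamma:
            c = z
            break
    if c is None:
        raise InfeasibleDesignError(
            f"no responder count at look n={look_n} reaches gamma={design.gamma}"
        )
    looks = prev_looks + (look_n,)
    while c <= look_n + 1:
        rule = StoppingRule(prev_bounds + (c,), t)
        if oc_exact(rule, looks, design.n_max, design.theta0).reject_prob <= design.alpha:
            break
        c += 1
    if c > look_n + 1:
        raise InfeasibleDesignError(
            f"no boundary at look n={look_n} meets the exact type I constraint "
            f"alpha={design.alpha}"
        )
    if c == look_n + 1:
        raise InfeasibleDesignError(
            f"boundary at look n={look_n} would stop with certainty (design invalid)"
        )
    return c


def build_rule(design: TrialDesign) -> StoppingRule:
    """Construct all interim boundaries of a design sequentially."""
    t = efficacy_threshold(design.n_max, design.theta0, design.alpha, design.dialect)
    rule = StoppingRule((), t)
    for look_n in design.interim_looks:
        c = stage_boundary(design, look_n, rule)
        rule = StoppingRule(rule.boundaries + (c,), t)
    return rule


def _equal_looks(n_max: int, k: int) -> tuple[int, ...]:
    """k analyses at (roughly) equal cumulative fractions of n_max, last = n_max."""
    return tuple(sorted({round(n_max * (j + 1) / k) for j in range(k)} | {n_max}))


def find_design(
    theta0: float,
    theta1: float,
    alpha: float,
    power_target: float,
    gamma: float = 0.5,
    prior: BetaPrior | None = None,
    n_looks: int | None = None,
    look_sizes: Sequence[int] | None = None,
    criterion: Literal["minimax", "optimal"] = "minimax",
    dialect: Dialect = "calibrated",
    n1_range: tuple[int, int] | None = None,
    scan_up: int = 15,
) -> DesignResult:
    """Search for a PS design meeting the alpha, power and gamma constraints.

    With ``look_sizes`` (cumulative, last = N_max) the schedule is fixed and
    only the boundaries are built.  With ``n_looks`` the maximum sample size
    is scanned around the normal-approximation seed; for two-stage designs
    every first-stage size n1 in ``n1_range`` (default 10..N_max-10) is
    tried, for more looks the schedule is equally spaced.  ``criterion``
    picks the feasible design minimizing N_max (minimax, ties by smaller
    E(N | theta0)) or E(N | theta0) (optimal, ties by smaller N_max then
    smaller first look).
    """
    prior = prior if prior is not None else flat_prior()

    def try_schedule(looks: Sequence[int]) -> DesignResult | None:
        looks = tuple(looks)
        try:
            design = TrialDesign(
                theta0=theta0,
                theta1=theta1,
                alpha=alpha,
                power_target=power_target,
                gamma=gamma,
                n_max=looks[-1],
                looks=looks,
                prior=prior,
                dialect=dialect,
            )
            rule = build_rule(design)
        except (InfeasibleDesignError, ValueError):
            return None
        oc = oc_summary(design, rule)
        if oc["type_i_error"] > alpha or oc["power"] < power_target:
            return None
        return DesignResult(design, rule, oc)

    if look_sizes is not None:
        res = try_schedule(look_sizes)
        if res is None:
            raise InfeasibleDesignError(
                f"schedule {tuple(look_sizes)} admits no boundary meeting "
                f"type I <= {alpha} and power >= {power_target}"
            )
        return res

    if n_looks is None or n_looks < 2:
        raise ValueError("give either look_sizes or n_looks >= 2")

    def candidates(n_max: int) -> list[tuple[int, ...]]:
        if n_looks == 2:
            lo, hi = n1_range if n1_range else (10, n_max - 10)
            return [(n1, n_max) for n1 in range(lo, hi + 1) if 0 < n1 < n_max]
        return [_equal_looks(n_max, n_looks)]

    def best_at(n_max: int) -> DesignResult | None:
        feas = [r for r in (try_schedule(s) for s in candidates(n_max)) if r is not None]
        if not feas:
            return None
        return min(feas, key=lambda r: (r.oc["expected_n_null"], r.design.looks[0]))

    # the seed only locates the scan; a vacuous power target still needs a finite one
    seed = initial_sample_size(theta0, theta1, alpha, min(max(power_target, 0.5), 0.99))
    # downward: least feasible N_max
    results: dict[int, DesignResult] = {}
    n = seed
    least_feasible = None
    while n >= max(n_looks, 2):
        r = best_at(n)
        if r is None:
            break
        results[n] = r
        least_feasible = n
        n -= 1
    if least_feasible is None:
        # seed itself infeasible: scan upward for the first feasible N_max
        n = seed + 1
        while n <= seed + scan_up and least_feasible is None:
            r = best_at(n)
            if r is not None:
                results[n] = r
                least_feasible = n
            n += 1
        if least_feasible is None:
            raise InfeasibleDesignError(
                f"no feasible design with N_max in [{max(n_looks, 2)}, {seed + scan_up}] "
                f"for alpha={alpha}, power>={power_target}, gamma={gamma}"
            )
    # upward from the seed until the optimum stops improving
    for n in range(seed + 1, seed + scan_up + 1):
        r = best_at(n)
        if r is not None:
            results[n] = r

    if criterion == "minimax":
        key = lambda r: (r.n_max, r.oc["expected_n_null"], r.design.looks[0])
    elif criterion == "optimal":
        key = lambda r: (r.oc["expected_n_null"], r.n_max, r.design.looks[0])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return min(results.values(), key=key)
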