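"""Lee–Liu predictive-probability (PP) futility design, the standard comparator.

At an interim look with z responders in n patients, PP is the posterior
predictive probability that, once all N_max patients are observed, the
posterior probability of the treatment beating theta0 exceeds a threshold
theta_T:

    PP = sum_y  P(Y = y | z, n)  *  1{ P(theta > theta0 | z + y, N_max) > theta_T }.

The trial stops for futility when PP falls below a cutoff (0.2 in the worked
comparisons here); at the final analysis the treatment is declared promising
when the posterior exceedance itself passes theta_T.  Side-by-side operating
characteristics against a PS rule on the same look schedule are produced by
:func:`compare_designs`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import BetaPrior, InterimData, posterior_update
from .oc import StoppingRule, oc_exact
from .satisfaction import EfficacyThreshold, TrialDesign, prediction_of_satisfaction

__all__ = [
    "PPConfig",
    "posterior_exceedance",
    "predictive_probability",
    "pp_boundary",
    "compare_designs",
]

THETA_T_GRID = tuple(np.round(np.arange(0.80, 0.995, 0.01), 2))


@dataclass(frozen=True)
class PPConfig:
    """PP design thresholds: final posterior cutoff theta_T, interim futility cutoff."""

    theta_t: float = 0.90
    pp_futility_threshold: float = 0.20

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_t < 1.0):
            raise ValueError(f"theta_t must lie in (0, 1), got {self.theta_t}")
        if not (0.0 <= self.pp_futility_threshold < 1.0):
            raise ValueError(
                f"pp_futility_threshold must lie in [0, 1), got {self.pp_futility_threshold}"
            )


def posterior_exceedance(post: BetaPrior, theta0: float) -> float:
    """P(theta > theta0) under a Beta posterior (regularized incomplete beta)."""
    if not (0.0 <= theta0 <= 1.0):
        raise ValueError(f"theta0 must lie in [0, 1], got {theta0}")
    return float(stats.beta.sf(theta0, post.a, post.b))


def predictive_probability(
    data: InterimData,
    n_max: int,
    prior: BetaPrior,
    theta0: float,
    theta_t: float,
) -> float:
    """Lee–Liu PP statistic; at n = n_max it degenerates to the pass indicator."""
    if data.n > n_max:
        raise ValueError(f"n={data.n} exceeds n_max={n_max}")
    m = n_max - data.n
    post = posterior_update(prior, data)
    y = np.arange(m + 1)
    # final posterior after z + y responders in n_max patients
    exceed = stats.beta.sf(theta0, prior.a + data.z + y, prior.b + n_max - data.z - y)
    mass = stats.betabinom.pmf(y, m, post.a, post.b)
    return float(min(1.0, mass[exceed > theta_t].sum()))


def _final_threshold(n_max: int, prior: BetaPrior, theta0: float, theta_t: float) -> int:
    """Smallest final responder total whose posterior exceedance passes theta_t."""
    z = np.arange(n_max + 1)
    exceed = stats.beta.sf(theta0, prior.a + z, prior.b + n_max - z)
    ok = np.nonzero(exceed > theta_t)[0]
    return int(ok[0]) if ok.size else n_max + 1


def pp_boundary(
    config: PPConfig,
    looks: Sequence[int],
    n_max: int,
    prior: BetaPrior,
    theta0: float,
) -> StoppingRule:
    """PP stopping rule: per interim look the smallest z allowed to continue.

    Continuation requires PP >= the futility cutoff; the final efficacy
    threshold is the smallest total whose posterior exceedance passes
    theta_T.  The responder count printed as the "stopping boundary" in
    worked comparisons is the largest *stopping* count, i.e. one less than
    each continuation boundary returned here.
    """
    t_eff = EfficacyThreshold(_final_threshold(n_max, prior, theta0, config.theta_t))
    bounds = []
    for n in looks:
        c = n + 1  # "always stop" sentinel
        for z in range(n + 1):
            pp = predictive_probability(InterimData(n=n, z=z), n_max, prior, theta0, config.theta_t)
            if pp >= config.pp_futility_threshold:
                c = z
                break
        bounds.append(c)
    return StoppingRule(tuple(bounds), t_eff)


def calibrate_theta_t(
    looks: Sequence[int],
    n_max: int,
    prior: BetaPrior,
    theta0: float,
    theta1: float,
    alpha: float,
    pp_futility_threshold: float = 0.20,
    grid: Sequence[float] = THETA_T_GRID,
) -> tuple[float, StoppingRule]:
    """Grid-calibrate theta_T: maximize exact power subject to exact type I <= alpha."""
    best: tuple[float, float, StoppingRule] | None = None
    for theta_t in grid:
        rule = pp_boundary(PPConfig(theta_t, pp_futility_threshold), looks, n_max, prior, theta0)
        if any(c > n for c, n in zip(rule.boundaries, looks)):
            continue
        if oc_exact(rule, looks, n_max, theta0).reject_prob > alpha:
            continue
        power = oc_exact(rule, looks, n_max, theta1).reject_prob
        if best is None or power > best[0]:
            best = (power, theta_t, rule)
    if best is None:
        raise RuntimeError(
            f"no theta_T in {grid[0]}..{grid[-1]} satisfies exact type I <= {alpha}"
        )
    return best[1], best[2]


def compare_designs(
    ps_rule: StoppingRule,
    pp_rule: StoppingRule,
    design: TrialDesign,
) -> pd.DataFrame:
    """Side-by-side OC of a PS and a PP rule on the design's look schedule.

    One row per rule: boundaries, prediction of satisfaction at the first
    continuation boundary, exact type I error, power and PET.
    """
    looks = design.interim_looks
    rows = []
    for name, rule in (("PS design", ps_rule), ("PP design", pp_rule)):
        at0 = oc_exact(rule, looks, design.n_max, design.theta0)
        at1 = oc_exact(rule, looks, design.n_max, design.theta1)
        z1 = rule.boundaries[0]
        pi = (
            prediction_of_satisfaction(InterimData(n=looks[0], z=z1), design)
            if z1 <= looks[0]
            else float("nan")
        )
        rows.append(
            {
                "method": name,
                "z_star": z1,
                "n1": looks[0],
                "t_eff": rule.t_eff.t_eff,
                "n_max": design.n_max,
                "ps_at_boundary": pi,
                "type_i_error": at0.reject_prob,
                "power": at1.reject_prob,
                "pet_null": at0.pet,
            }
        )
    return pd.DataFrame(rows).set_index("method")
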