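"""Seeded Monte Carlo trial simulator — a stochastic check on the exact OC.

Each replicate draws per-patient Bernoulli responses, walks the look
schedule applying the stop-iff-below-boundary rule, and records where the
trial stopped, whether it rejected at the final analysis, and its realized
sample size.  Empirical rates carry binomial standard errors, so agreement
with the dynamic-programming OC within a few SE validates both routes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .oc import StoppingRule, _validate

__all__ = ["SimResult", "simulate_trials"]


@dataclass(frozen=True)
class SimResult:
    n_sims: int
    seed: int
    theta: float
    reject_prob: float
    reject_se: float
    pet: float
    pet_se: float
    stop_by_stage: tuple[float, ...]
    expected_n: float
    expected_n_se: float


def simulate_trials(
    rule: StoppingRule,
    looks: Sequence[int],
    n_max: int,
    theta: float,
    n_sims: int,
    seed: int,
) -> SimResult:
    """Simulate ``n_sims`` trials under true response rate ``theta``.

    Fully vectorized: all per-patient responses are drawn up front from a
    single named generator, so results are reproducible from the seed alone
    and independent of evaluation order.
    """
    looks = _validate(rule, looks, n_max)
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    responses = rng.random((n_sims, n_max)) < theta
    cum = np.cumsum(responses, axis=1)

    active = np.ones(n_sims, dtype=bool)
    stop_stage = np.full(n_sims, -1)  # -1 = reached the final analysis
    sample_size = np.full(n_sims, n_max)
    for k, (c, n) in enumerate(zip(rule.boundaries, looks)):
        stopped = active & (cum[:, n - 1] < c)
        stop_stage[stopped] = k
        sample_size[stopped] = n
        active &= ~stopped
    reject = active & (cum[:, n_max - 1] >= rule.t_eff.t_eff)

    def rate_se(p: float) -> float:
        return float(np.sqrt(p * (1.0 - p) / n_sims))

    pet = float(np.mean(stop_stage >= 0))
    rej = float(np.mean(reject))
    stop_by_stage = tuple(float(np.mean(stop_stage == k)) for k in range(len(looks)))
    en = float(np.mean(sample_size))
    en_se = float(np.std(sample_size, ddof=1) / np.sqrt(n_sims)) if n_sims > 1 else 0.0
    return SimResult(
        n_sims=n_sims,
        seed=seed,
        theta=theta,
        reject_prob=rej,
        reject_se=rate_se(rej),
        pet=pet,
        pet_se=rate_se(pet),
        stop_by_stage=stop_by_stage,
        expected_n=en,
        expected_n_se=en_se,
    )
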