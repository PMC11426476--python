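"""Independent brute-force oracles used to validate the fast implementations.

Everything here deliberately avoids the code paths (and where feasible the
scipy distributions) it is used to check: tail sums accumulate explicit pmf
products, the beta-binomial comes from a recursive ratio or sequential
path probabilities, and operating characteristics enumerate every binary
response sequence.
"""

from __future__ import annotations

import itertools
import math


def binom_pmf_direct(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def binom_cdf_sum(k: int, n: int, p: float) -> float:
    return sum(binom_pmf_direct(i, n, p) for i in range(0, min(k, n) + 1)) if k >= 0 else 0.0


def binom_sf_sum(k: int, n: int, p: float) -> float:
    return sum(binom_pmf_direct(i, n, p) for i in range(max(k, 0), n + 1))


def betabinom_pmf_ratio(m: int, a: float, b: float) -> list[float]:
    """Whole beta-binomial pmf from P(0) and the ratio recurrence."""
    p0 = 1.0
    for j in range(m):
        p0 *= (b + j) / (a + b + j)
    out = [p0]
    for y in range(m):
        out.append(out[-1] * (m - y) * (a + y) / ((y + 1) * (b + m - y - 1)))
    return out


def _path_prob(bits: tuple[int, ...], a: float, b: float) -> float:
    """Probability of one future response sequence under a Beta(a, b) posterior."""
    p = 1.0
    for x in bits:
        p *= (a if x else b) / (a + b)
        a, b = (a + 1, b) if x else (a, b + 1)
    return p


def ps_enumeration(
    z: int, n: int, n_max: int, theta0: float, t_eff: int, a: float, b: float
) -> float:
    """Prediction of satisfaction by exhaustive enumeration of future sequences.

    Sums, over every binary sequence of the m* remaining patients, the path
    probability under the sequentially-updated posterior times the binomial
    cdf weight of the sequence total, restricted to totals reaching t_eff.
    """
    m = n_max - n
    ap, bp = a + z, b + n - z
    total = 0.0
    for bits in itertools.product((0, 1), repeat=m):
        y = sum(bits)
        if z + y < t_eff:
            continue
        w = binom_cdf_sum(y, m, theta0)
        total += w * _path_prob(bits, ap, bp)
    return total


def oc_enumeration(
    boundaries: tuple[int, ...], looks: tuple[int, ...], n_max: int, t_eff: int, theta: float
) -> dict:
    """Operating characteristics by enumerating every per-patient response path."""
    reject = 0.0
    stop = [0.0] * len(looks)
    en = 0.0
    for bits in itertools.product((0, 1), repeat=n_max):
        p = theta ** sum(bits) * (1.0 - theta) ** (n_max - sum(bits))
        stopped = False
        for k, (c, n) in enumerate(zip(boundaries, looks)):
            if sum(bits[:n]) < c:
                stop[k] += p
                en += n * p
                stopped = True
                break
        if not stopped:
            en += n_max * p
            if sum(bits) >= t_eff:
                reject += p
    pet = sum(stop)
    return {"reject_prob": reject, "pet": pet, "stop_by_stage": tuple(stop), "expected_n": en}


def beta_sf_integrate(theta0: float, a: float, b: float, steps: int = 200_000) -> float:
    """P(theta > theta0) for Beta(a, b) by composite Simpson integration."""
    # integrate the pdf on [theta0, 1]; log-gamma normalization, plain Simpson
    lognorm = math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)

    def pdf(x: float) -> float:
        if x <= 0.0 or x >= 1.0:
            return 0.0
        return math.exp(lognorm + (a - 1) * math.log(x) + (b - 1) * math.log(1 - x))

    h = (1.0 - theta0) / steps
    acc = pdf(theta0) + pdf(1.0 - 1e-15)
    for i in range(1, steps):
        acc += (4 if i % 2 else 2) * pdf(theta0 + i * h)
    return acc * h / 3.0
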