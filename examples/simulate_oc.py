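"""Monte Carlo validation of the exact operating characteristics.

Simulates 100,000 two-stage trials (boundary 11 of 25, efficacy from 20 of
50) at several true response rates and prints the empirical rejection rate
and early-termination probability next to the exact dynamic-programming
values.  Agreement within a few standard errors validates both routes.
"""

from psdesign import (
    EfficacyThreshold,
    StoppingRule,
    oc_exact,
    simulate_trials,
)

rule = StoppingRule((11,), EfficacyThreshold(20))
print(f"{'theta':>6} {'reject(MC)':>11} {'reject(exact)':>14} {'PET(MC)':>8} {'PET(exact)':>11}")
for theta in (0.1, 0.3, 0.5, 0.7):
    sim = simulate_trials(rule, (25,), 50, theta, n_sims=100_000, seed=42)
    exact = oc_exact(rule, (25,), 50, theta)
    print(
        f"{theta:6.2f} {sim.reject_prob:11.4f} {exact.reject_prob:14.4f} "
        f"{sim.pet:8.4f} {exact.pet:11.4f}"
    )
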