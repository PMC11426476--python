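"""PS design vs the Lee-Liu predictive-probability (PP) design.

Both rules monitor the same 40-patient lung-cancer trial (30% vs 50%
response rate, one look after 20) with a flat prior.  The PP rule stops
when the predictive probability of a positive final posterior conclusion
(theta_T = 0.90) drops below 20%.  The PS rule terminates more readily
(higher PET under the null) at the price of some power — the pattern
expected from its stricter use of the final p-value.
"""

from psdesign import (
    PPConfig,
    TrialDesign,
    build_rule,
    compare_designs,
    flat_prior,
    pp_boundary,
)

design = TrialDesign(
    theta0=0.3, theta1=0.5, alpha=0.05, power_target=0.8, gamma=0.5,
    n_max=40, looks=(20, 40), prior=flat_prior(),
)
ps_rule = build_rule(design)
pp_rule = pp_boundary(PPConfig(theta_t=0.90, pp_futility_threshold=0.20),
                      looks=(20,), n_max=40, prior=flat_prior(), theta0=0.3)

table = compare_designs(ps_rule, pp_rule, design)
print(table.round(4))
print("\n(z_star is the smallest responder count at the look that continues;"
      "\n the trial stops for futility at z_star - 1 or fewer.)")
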