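"""Build and evaluate the classic two-stage futility design.

30% vs 50% response rate, one look after 25 of 50 patients, futility
threshold gamma = 0.5 on the prediction of satisfaction.  At alpha = 0.05
the design stops at look 1 below 11 responders and declares efficacy from
20 of 50; its exact type I error, power, early-termination probability and
expected sample sizes are printed below the boundaries.
"""

from psdesign import TrialDesign, build_rule, flat_prior, oc_summary

for alpha in (0.05, 0.10):
    design = TrialDesign(
        theta0=0.3, theta1=0.5, alpha=alpha, power_target=0.8, gamma=0.5,
        n_max=50, looks=(25, 50), prior=flat_prior(),
    )
    rule = build_rule(design)
    oc = oc_summary(design, rule)
    print(f"alpha = {alpha}:")
    print(f"  continue at look 1 iff z >= {rule.boundaries[0]}; "
          f"efficacy iff final total >= {rule.t_eff.t_eff}")
    print(f"  exact type I error {oc['type_i_error']:.4f}, power {oc['power']:.4f}")
    print(f"  PET(theta0) = {oc['pet_null']:.4f}, "
          f"E(N|theta0) = {oc['expected_n_null']:.2f}, "
          f"E(N|theta1) = {oc['expected_n_alt']:.2f}")
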