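"""Elicit a beta design prior from an anticipated response rate and a CV.

An investigator who expects a 30% response rate and is confident in it
(coefficient of variation 10%) gets a Beta(69.7, 162.63) prior — about 232
pseudo-patients of prior information.  Doubling the CV cuts that weight
roughly fourfold.
"""

from psdesign import ElicitationInput, describe_prior, elicit_beta

for cv in (0.10, 0.25, 0.50):
    prior = elicit_beta(ElicitationInput(mean=0.3, cv=cv))
    d = describe_prior(prior)
    print(
        f"mean 0.30, CV {cv:4.0%}:  Beta(a={d['a']:8.3f}, b={d['b']:8.3f})  "
        f"weight a+b = {d['a'] + d['b']:7.1f} patients,  "
        f"95% interval ({d['ci95'][0]:.3f}, {d['ci95'][1]:.3f})"
    )
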