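"""Prediction of satisfaction at a first interim look.

A single-arm trial tests a 30% null response rate at alpha = 0.10 with a
planned maximum of 27 patients and one look after 10.  For every possible
responder count z at the look, the table prints pi(z) — the predictive
probability-weighted satisfaction with the final result — under a flat
Beta(1,1) prior and under an informative prior (anticipated rate 0.5,
CV 10%).  The trial continues only while pi >= 0.5: the flat-prior rule
needs 4 responders to continue, the informative one only 3.
"""

from psdesign import (
    ElicitationInput,
    TrialDesign,
    elicit_beta,
    flat_prior,
    ps_table,
)

design = TrialDesign(
    theta0=0.3, theta1=0.5, alpha=0.10, power_target=0.8, gamma=0.5,
    n_max=27, looks=(10, 27), prior=flat_prior(),
)
informative = elicit_beta(ElicitationInput(mean=0.5, cv=0.10))

table = ps_table(
    design,
    n_interim=10,
    scenarios=[
        ("flat, Nmax=27", flat_prior(), 27),
        ("flat, Nmax=32", flat_prior(), 32),
        ("informative, Nmax=27", informative, 27),
    ],
)
print(table.round(6))
for col in table:
    z_cont = int((table[col] >= design.gamma).idxmax())
    print(f"{col}: continue from z >= {z_cont}")
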