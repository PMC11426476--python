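# psdesign

Futility monitoring for single-arm phase II trials with a binary endpoint,
built around the **prediction of satisfaction (PS)** statistic — a hybrid
frequentist–Bayesian interim monitor that controls the final-analysis type I
error exactly while using the Bayesian posterior predictive distribution to
decide whether a trial is still worth continuing.

## The method

A trial enrols up to `N_max` patients and tests

    H0: theta <= theta0   vs   H1: theta > theta0

on the total responder count `Z ~ Binomial(N_max, theta)`.  Efficacy is
declared at the end when `Z >= q_alpha`, the smallest total whose exact null
tail probability is within `alpha`.  The *satisfaction index*

    phi(z) = (1 - p(z)) * 1{z >= q_alpha},      p(z) = P(Z >= z | theta0),

is zero outside the rejection region and otherwise grows with the
significance of the final result.  At an interim look with `z` responders
among `n` patients, the **prediction of satisfaction** averages the
satisfaction weight over the beta-binomial posterior predictive distribution
of the `Y` responders still to come among the `m* = N_max - n` remaining
patients:

    pi(z) = sum_{y=(q_alpha - z)+}^{m*}  B(y; m*, theta0) * nu(y | z, n),

where `B` is the binomial cdf and `nu` the beta-binomial predictive pmf
under the conjugate Beta posterior.  The trial stops for futility as soon as
`pi` falls below a threshold `gamma` (typically 0.5).  Boundaries derived
from this rule are then checked — and if necessary raised — against the
design's *exact* multi-look type I error, computed by dynamic programming
over the cumulative responder count.

The package covers the full design workflow:

- **Prior elicitation** from an anticipated response rate and a coefficient
  of variation (`elicit_beta`), e.g. mean 0.3 with CV 10% gives
  Beta(69.7, 162.63).
- **Interim monitoring** (`prediction_of_satisfaction`, `ps_table`).
- **Design construction** (`stage_boundary`, `build_rule`, `find_design`):
  per-look futility boundaries, a normal-approximation sample-size seed, and
  minimax / optimal search over `N_max` and the first-stage size.
- **Exact operating characteristics** (`oc_exact`, `oc_summary`): rejection
  probability, probability of early termination (PET), expected sample size
  at any true response rate; classical 2-/3-stage closed forms as
  cross-checks (`oc_closed_form`).
- **Monte Carlo validation** (`simulate_trials`), seeded and vectorized.
- **Lee–Liu predictive-probability comparator** (`predictive_probability`,
  `pp_boundary`, `compare_designs`).

## Worked example

```python
from psdesign import TrialDesign, build_rule, flat_prior, oc_summary

design = TrialDesign(
    theta0=0.3, theta1=0.5, alpha=0.05, power_target=0.8, gamma=0.5,
    n_max=50, looks=(25, 50), prior=flat_prior(),
)
rule = build_rule(design)
oc = oc_summary(design, rule)
print(rule.boundaries, rule.t_eff.t_eff)
print(round(oc["type_i_error"], 4), round(oc["power"], 4), round(oc["pet_null"], 4))
```

prints

```
(11,) 20
0.043 0.7759 0.9022
```

i.e. the 30% vs 50% two-stage design stops for futility with 10 or fewer
responders among the first 25 patients, declares efficacy from 20 of 50
responders, has exact type I error 4.3%, power 77.6%, and — under the null
— terminates early 90.2% of the time, for an expected sample size of 27.4
patients instead of 50.

The same workflow is available from the shell:

```sh
psdesign design --theta0 0.3 --theta1 0.5 --alpha 0.05 --power 0.7 \
    --looks 25,50 --out design.json
psdesign oc --design design.json --theta-grid 0.1:0.7:0.1
psdesign simulate --design design.json --theta 0.5 --n-sims 100000 --seed 42
psdesign compare-pp --design design.json --pp-cutoff 0.2 --theta-t 0.90
```

Each script in `examples/` demonstrates one capability end to end and
prints a line explaining the numbers.

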