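# Methods

## Model and monitoring statistic

Patients respond independently with unknown probability `theta`; the trial
tests `H0: theta <= theta0` against `theta > theta0` on the responder total
out of at most `N_max` patients, with a conjugate Beta(a, b) prior on
`theta`.  The final-analysis rejection region is `{Z >= t_eff}` with

    t_eff = min{ u : P(Z > u | N_max, theta0) <= alpha },

the smallest total whose *strict* null upper tail is within `alpha`; the
achieved (exact) size is therefore at most the nominal level.  The
satisfaction index of a final result `z` is `1 - P(Z >= z | theta0)` inside
the region and 0 outside.

At an interim look `(n, z)` the prediction of satisfaction is

    pi(z) = sum_{y = max(t_eff - z, 0)}^{m*}  B(y; m*, theta0) * nu(y | z, n),

with `m* = N_max - n`, `B(.; m*, theta0)` the binomial cdf on the remaining
sample and `nu` the beta-binomial predictive pmf under the updated
posterior Beta(a + z, b + n - z).  `pi` is a probability-weighted
"satisfaction with the final result if we continue": it is 0 when the
rejection region is out of reach, approaches 1 when efficacy is nearly
certain, and is nondecreasing in `z`.  It is defined at any interim `n`,
not just scheduled looks, because nothing in the formula references the
schedule.

### Threshold and summation conventions

Two off-by-one readings exist for the efficacy threshold (strict vs weak
null tail) and for the upper limit of the binomial-cdf weight (`y` vs
`y - 1`).  The package's default, the `calibrated` dialect (strict tail,
upper limit `y`), is the unique combination that reproduces all the
published worked values this implementation was checked against: efficacy
thresholds 20/19 (N_max = 50, theta0 = 0.3, alpha = 0.05/0.10), 17 and 6
for the two 40-patient lung-cancer cohorts, and the flat-prior first-look
pi-table to < 1e-7 for z >= 1.  The `literal` dialect (weak tail, upper
limit `y - 1`) is retained on every API surface for comparison.  One
published table cell is knowingly not reproduced: the informative-prior
column of the first-look table behaves as if computed with Beta(51, 51)
rather than the Beta(49.5, 49.5) that the stated elicitation yields; the
package follows the elicitation formula, which is self-consistent and
reproduces the published hyper-parameter pair (69.7, 162.63) at mean 0.3.

## Prior elicitation

From an anticipated rate `mean` and coefficient of variation `cv`
(sd/mean, as a fraction):

    a = (1 - mean) / cv^2 - mean,     b = a (1/mean - 1).

Beta(a, b) then has exactly the stated mean and cv (checked algebraically
and by a round-trip property test).  `cv` beyond `sqrt((1-mean)/mean)`
admits no beta distribution and raises, naming the admissible bound.
CV values above 1 given on the command line are read as percentages with a
logged note.

## Stopping rules and boundary construction

A design's stopping rule holds one continuation boundary `c_k` per interim
look — stop for futility iff cumulative responders `< c_k` — plus `t_eff`.
Each boundary is constructed as

1. the smallest `z` with `pi(z) >= gamma` at that look, then
2. raised by the smallest amount making the exact type I error of the
   partial design (all boundaries fixed so far plus this one, final
   threshold `t_eff`) at most `alpha`.

Step 2 matters: in the 25/50 two-stage design at alpha = 0.05 the smallest
PS-qualifying count is 10, but that rule's exact size is ~0.060, so the
operative boundary is 11.  Boundaries are monotone in `gamma` and never
decrease when `alpha` tightens (both property-tested).  A boundary equal to
the look size + 1 would stop with certainty and is rejected as infeasible.

`gamma` defaults to 0.5 and must lie in [0.5, 1]: continuation should
require at least an even predictive chance of a satisfying conclusion.
The design is futility-only — a high `pi` never triggers early efficacy
claims, which early-phase sample sizes cannot support.

## Sample-size search

The `N_max` scan seeds at the one-stage normal approximation

    N0 = ceil( theta~ (1 - theta~) [(u_{1-alpha} + u_{1-beta}) / (theta1 - theta0)]^2 ),
    theta~ = (theta0 + theta1)/2,

(for 0.3 vs 0.5 at alpha = 0.10, power 0.80: N0 = 28), scans downward to
the least `N_max` admitting a valid rule, then upward a fixed window
(default 15) past the seed.  For two-stage designs every first-stage size
`n1` in 10..N_max-10 is tried; for more looks the schedule is equally
spaced.  `minimax` returns the feasible design with the smallest `N_max`
(ties by smaller null-expected sample size), `optimal` the one minimizing
E(N | theta0) (ties by smaller `N_max`, then smaller first look).  The seed
only positions the scan; it cannot change which design wins, only runtime.

## Operating characteristics

Exact OC come from forward dynamic programming over the cumulative
responder count: the state distribution is pushed look to look by binomial
increments, sub-boundary mass is harvested per stage, and the surviving
final-state mass is scored against `t_eff`.  Expected sample size is the
stop-mass-weighted sum of look sizes plus `N_max` times the probability of
reaching the end.  The DP is validated three independent ways in the test
suite: exhaustive enumeration of all `2^N_max` response paths for
`N_max <= 12` (agreement to 1e-12), the classical two- and three-stage
closed-form sums (1e-12), and a seeded Monte Carlo simulator at 1e5
replicates (3 standard errors).  The closed forms read the early-stage
cdf terms as `P(Z < c_k)` — the stop-iff-strictly-below convention that
matches the DP and the published PET of 0.90 for the two-stage design
(the stop-at-or-below reading would give 0.956).

## Predictive-probability comparator

The Lee–Liu design stops when

    PP = sum_y nu(y | z, n) * 1{ P(theta > theta0 | z + y, N_max) > theta_T }

drops below a futility cutoff (0.2 in the worked comparisons), and declares
final efficacy when the posterior exceedance itself passes `theta_T`.
`theta_T` defaults to 0.90, a conventional choice that reproduces the
published boundary patterns of both 40-patient lung-cancer cohorts (stop at
<= 6 of 20 with final threshold 16 of 40 at theta0 = 0.3; stop at <= 1 of
20 with final threshold 5 of 40 at theta0 = 0.07); any `theta_T` in
(0.862, 0.921] gives the same first pattern.  A grid auto-calibration
(maximize exact power subject to exact type I <= alpha over
theta_T in {0.80, 0.81, ..., 0.99}) is available but not the default,
because on these cohorts it selects stricter thresholds (0.96) and
different boundaries than the published comparison.  Note that comparison
tables in the field print the PP rule's largest *stopping* count where PS
rules print the smallest *continuing* count; `pp_boundary` returns
continuation boundaries throughout for internal consistency, so the printed
"6" corresponds to a returned boundary of 7.

## Numerical choices

- All distribution evaluations go through scipy's binomial, beta-binomial
  and beta implementations (log-gamma based, stable in the far tails,
  non-integer hyper-parameters supported).  Responder counts are exact
  integers everywhere.
- Upper tails use the survival function directly rather than `1 - cdf`.
- `pi` and PP are clamped to [0, 1] against last-ulp spill from summing a
  full predictive support.
- Ties in the design search are broken deterministically (documented order),
  so repeated runs return the identical design.
- Degenerate inputs are contractual errors, not silent answers: interim
  data with `n >= N_max`, boundaries exceeding a look size + 1, elicitation
  outside the admissible region, and invalid probabilities all raise with
  the offending quantity named.

## Problem sizes used in the validation suite

Exhaustive path enumeration is run up to `N_max = 12` (4096 paths) and
interim enumeration up to 12 remaining patients; Monte Carlo checks use
1e5 replicates (standard errors ~0.0015 on a probability near 0.5); design
searches in tests use the 0.3 vs 0.5 configuration with `N_max` around
20–45.  These sizes exercise every code path at full precision while
keeping the suite fast.

## What the checks do and do not show

All validation here is against exact finite-sample binomial computation and
published worked designs — there is no data-generating model beyond
independent Bernoulli responses with a fixed `theta`.  Real trials can
violate that (response drift over enrolment, cohort heterogeneity,
evaluation lag between enrolment and response assessment); the operating
characteristics computed here are exact for the idealized sampling model
only.  In particular, interim looks are assumed to happen exactly at the
scheduled cumulative sample sizes with all responses observed; staggered
entry with pending responses would need the look schedule re-interpreted in
evaluable patients.

## Known limitations

- Early stopping is for futility only; no efficacy boundaries.
- The multi-look search beyond two stages fixes equally spaced schedules
  rather than searching all schedule partitions (combinatorially large and
  not needed for the supported design space).
- Published multi-stage boundary tables for this method contain
  internal inconsistencies (their two-stage columns are reproduced exactly;
  their three- and five-stage columns disagree with their own stated
  construction under any off-by-one convention we tried, in a pattern
  suggesting swapped columns).  The package trusts its own
  enumeration-validated construction for k > 2.
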