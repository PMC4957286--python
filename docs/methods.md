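# Methods

## Decision problem and model structure

The model compares two strategies for a cohort of people recruited to a
free leisure-centre membership programme: *intervention* (the programme
is offered; a fraction completes it and becomes more active for a limited
time) and *control* (no programme; everyone keeps their baseline activity
level). Outcomes are lifetime discounted costs (GBP, payer perspective)
and QALYs per recruited person.

The state space is `healthy`, `CHD`, `stroke`, `diabetes`, `dead`.
Everyone starts healthy at the starting age (default 45). Once a month a
healthy person can have a first CHD, stroke or diabetes event or die of
background causes; disease states are absorbing apart from death (no
between-disease transitions, no recurrent events); `dead` is absorbing.
The cohort runs until extinction, with a hard cap at age 110 where any
remaining occupancy (numerically negligible) is moved to `dead`.

CHD and stroke carry a 12-month tunnel after onset: during the first year
the "first event" utility multiplier applies, afterwards the "post event"
multiplier. The tunnel exists for utility only — management costs and
post-event mortality are the same inside and outside it, and the one-off
acute cost is charged once in the incidence cycle.

## Transitions

* Yearly incidence rates for the low-activity population are age-banded
  (printed bands end at 81; lookups clamp at both ends, so ages beyond
  the last band reuse its value — the only defensible extension absent
  data). Rates convert to monthly probabilities by the constant-hazard
  map `p = 1 − exp(−r/12)`; at these magnitudes this is indistinguishable
  from `r/12` but stays valid for large inputs.
* Activity scales incidence multiplicatively: `RR_d(moderate)` and
  `RR_d(high)` versus low, with no residual protection after the activity
  level reverts.
* A fraction of CHD and stroke events is immediately fatal
  (age-banded); fatal events still incur the acute event cost (acute
  care is incurred either way — a modelling choice, as the source
  convention is not stated).
* Background mortality comes from a life table giving the monthly
  all-cause death probability `q(a)` and the CVD share of deaths `s(a)`.
  The all-cause hazard `h = −ln(1−q)` is split into `h·s` (CVD) and
  `h·(1−s)`; post-event relative risks multiply these cause-specific
  hazards, so probabilities remain valid under arbitrarily large
  multipliers, and the pair recombines to `q` exactly when both RRs are 1.
* Competing exits from a state are summed; in the (never attained)
  event the sum exceeds 1 it is proportionally normalized. Rows
  therefore always sum to 1 and occupancy mass is conserved to machine
  precision (the engine asserts < 1e-9 drift over the full horizon).

## Utilities and costs

Utility per alive state-year is `u_age(a) · m_state + mh(level)`, clamped
to [0, 1]. Disease weights are interpreted as *multipliers* on the
age-specific healthy utility rather than absolute values (the post-CHD
weight 0.92 exceeds the healthy baseline at most ages, so the absolute
reading would be incoherent). The mental-wellbeing gain `mh` is additive,
disease-independent, and follows the person's *current* activity level:
0.023 QALY/yr when moderately and 0.104 when highly active, derived as
`extra_hours × 2 half-hours × 52 weeks × 0.000222433333` (52 weeks per
year reproduces the printed roundings). No half-cycle correction is
applied; with monthly cycles its effect is far below other uncertainties.
Cycle accrual uses beginning-of-cycle occupancy; costs and QALYs are
discounted by `(1.035)^(−t)` with `t` in years from model start.

Programme costs accrue undiscounted at time zero (they arise within the
first four months; discounting a 4-month stream at 3.5 %/yr changes the
total by well under 1 %): £38.30 general cost per recruit, £97 per
completer, £16.75 average per non-completer. The £16.75 average is used
as a primitive input; the stage-ledger helper
(`noncompleter_cost_from_ledger`) exists for the synthetic pipeline and
audits, with its stage→cost allocation explicitly configurable, because
no published allocation reconciles the per-stage components with that
average (plausible allocations give ≈£22).

## Arms and the duration of effect

Completers (15.5 % = 159/1025) hold their end-of-programme activity
distribution (23.5/23.5/52.9 %) for `D` months in total (base 12) and
then revert to the overall baseline distribution (32.4/37.6/30.0 %);
everyone else stays at baseline throughout. Because the joint
(follow-up, baseline) distribution of completers is not observed, the
reversion uses the independence coupling: weight `c · f_i · b_j` for the
pathway "level *i* before month D, level *j* after". This is
assumption-minimal but *path-dependent*: with follow-up equal to
baseline the two arms coincide only in distribution, leaving a
second-order ΔQALY residue of order 1e-6 (verified by test) rather than
exactly zero.

In one-way sweeps an activity fraction is varied against the *low*
(inactive) pool, holding the other active level fixed — the reading
under which "fewer people already active at baseline" makes the
programme look better, consistent with the published threshold
directions. Varying the low share renormalizes the active levels
proportionally.

## Background-mortality generator

The bundled life table is synthetic: a Gompertz annual hazard
`μ(a) = exp(−10.3 + 0.094·a)` (so `q(a) = 1 − exp(−μ/12)` monthly) with
CVD death share `clamp(0.05 + 0.003·(a−30), 0.05, 0.35)`. The defaults
approximate contemporary UK all-cause mortality at mid and old age. What
it does **not** reproduce is the exact age profile of the unpublished
national table behind the original analysis; absolute per-arm totals
(total lifetime cost, life-years, QALYs) therefore carry a residual error
of a few percent — our control arm's lifetime disease cost comes out ~7 %
lower, because the Gompertz tail kills slightly more people before the
high-incidence ages. The *incremental* quantities are insensitive to
this choice (the programme's effect is concentrated in the first year of
the model), which is why they are reproduced to well under 1 % (Δcost)
and a few percent (ICER ≈ +3 %). Any real table can be supplied as
`age,q_month,cvd_share` text via `read_life_table` / `--life-table`.

## Sensitivity analyses

Every scalar with a printed lower/upper range participates. The range is
read as a 95 % interval, so `sd = (upper − lower)/3.92`.

* **beta** (probabilities, utilities): method of moments around
  `mean = base`; infeasible moments fall back to uniform on the range
  with a logged warning.
* **gamma** (costs): method of moments, `shape = (mean/sd)²`.
* **lognormal** (relative risks): median = base,
  `log-sd = (ln upper − ln lower)/3.92`.
* **Dirichlet** (activity compositions, drawn jointly): mean = base
  fractions, concentration 100 (moderate sampling variation consistent
  with the printed marginal ranges; configurable).
* **uniform** (duration of effect, 4–20 months) and **normal**
  (starting age, rounded to whole years and clamped to 25–65).

Draws may legitimately leave the printed range (they are tails of the
fitted distributions); post-event mortality multipliers are floored at 1.
One master seed spawns an independent substream per draw, so PSA results
are independent of chunking and evaluation order. Cost-effectiveness of
a draw at willingness-to-pay λ is defined by positive net monetary
benefit — the coherent criterion in all four quadrants (a draw losing
QALYs counts only where its savings outweigh the loss).

Threshold search uses bisection on NMB(λ) over a parameter's range
(equivalent to ICER = λ whenever QALYs are gained); for integer-resolution
parameters (duration in months, starting age in years) a whole-number
grid scan returns the first cost-effective integer. The ICER is
non-monotone in starting age at age-band edges, which is why the age
threshold comes from the grid scan rather than bisection.

## Synthetic participant cohort

The generator emulates the participant-level process the aggregates
summarise: baseline levels multinomial at the baseline fractions;
completion Bernoulli; dropout stage multinomial proportional to the
dropout ledger (300/280/138/107/41); completers' follow-up level
multinomial at the follow-up fractions, observed only for a configurable
response fraction (default 52/159, missing at random); questionnaire
answers drawn from level-conditional ranges and verified to score back to
the assigned level under the standard short-form categorical protocol
(MET-minutes `8·vig + 4·mod + 3.3·walk`, sessions under 10 min/day
discarded; thresholds are module constants so another scoring dialect can
be swapped in). It does **not** model selective non-response, seasonal
activity patterns, or within-programme attendance dynamics — so passing
recovery tests shows the estimators and plumbing are correct, not that
real questionnaire data would be this clean.

## Problem sizes and numerical conventions

The deterministic base case simulates 9 activity-pathway strata over 780
monthly cycles (ages 45–110) and runs in ~0.1 s; both arms reweight one
shared set of stratum runs. The PSA evaluates 5000 draws in batches of
250 through the same vectorized engine (~30 s). Tests use a shortened
horizon (age 55) where full lifetime runs add nothing. Tolerances:
occupancy conservation 1e-9 over the horizon; closed-form geometric
checks 1e-10; recovery experiments use binomial/Monte-Carlo bands derived
from their sample sizes.

## Known limitations

* The synthetic life table bounds the fidelity of *absolute* totals (see
  above); only incremental results should be compared across life tables.
* The independence coupling for completers' reversion is an assumption;
  completers' own baseline distribution (unpublished) would be the
  correct reversion target and could shift ΔQALY by a few percent.
* Only three diseases are modelled, all-healthy start, no recurrent
  events — inherited simplifications of the decision problem.
* The PSA parameterization (95 %-interval reading, independence except
  the Dirichlet blocks) is one defensible choice among several; CEAC
  probabilities are sensitive to it at the ±5-percentage-point level
  because several of the printed ranges are very wide and right-skewed.
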