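# pacea — cost-utility model for a leisure-centre activity programme

`pacea` is a health-economic decision model for evaluating a free
leisure-centre membership programme offered to physically inactive adults.
It asks the standard adoption question: given what the programme costs per
recruited person and how it shifts the recruits' physical-activity levels,
is the gain in quality-adjusted life-years (QALYs) worth paying for at a
willingness-to-pay of £20,000 per QALY?

The core is a monthly-cycle Markov cohort model with states
*healthy → {coronary heart disease, stroke, type II diabetes} → dead*,
run from the cohort's starting age (45) until extinction. Physical
activity acts through two channels:

* **disease risk** — age-specific yearly incidence rates `r_d(a)` for the
  low-activity population are converted to monthly probabilities
  `1 − exp(−r_d(a)/12)` and multiplied by relative risks `RR_d(level) ≤ 1`
  for moderately/highly active people;
* **mental wellbeing** — an additive utility gain while active, derived
  from a gain of 0.000222433333 QALY per extra weekly half-hour of
  activity sustained over a year (0.023 QALY/yr when moderately active,
  0.104 when highly active).

Utility in a state is `u_age(a) · m_state + mh(level)`, clamped to 1,
where `m_state` is a disease multiplier with a 12-month "first year after
event" tunnel for CHD and stroke. Survived events raise subsequent
cause-specific background mortality (e.g. CVD mortality ×3.89 after CHD),
applied on the hazard scale to a cause-split life table. Costs (acute
event, annual disease management, programme delivery) and QALYs are
discounted at 3.5 %/yr. Incremental results are summarised as
`ICER = ΔC/ΔQ` and net monetary benefit `NMB(λ) = λ·ΔQ − ΔC`.

Around the deterministic base case the package provides one-way
sensitivity sweeps with threshold search (the parameter value at which the
ICER crosses λ), a 5000-draw probabilistic sensitivity analysis with
cost-effectiveness acceptability curves, and a synthetic participant-level
cohort generator (short-form activity-questionnaire answers, completion /
dropout, per-stage costs) with estimators that recover the aggregate model
inputs — so the whole pipeline is testable end to end without any
external data. Background mortality comes from a bundled synthetic
Gompertz life table (a stand-in for unpublished national statistics) and
can be replaced by any real table supplied as delimited text.

## Worked example

```python
from pacea import (load_default_parameters, default_life_table,
                   build_arms, run_cohort, incremental)

mp = load_default_parameters()          # bundled base-case inputs
lt = default_life_table()               # synthetic background mortality
intervention, control = build_arms(mp.programme)
cea = incremental(run_cohort(intervention, mp, lt),
                  run_cohort(control, mp, lt))
print(f"dC={cea.delta_cost:.2f} dQ={cea.delta_qaly:.4f} ICER={cea.icer:,.0f}")
```

prints

```
dC=67.26 dQ=0.0032 ICER=20,969
```

i.e. per recruited person the programme costs an extra £67.26 (its £67.50
delivery cost less ~£0.24 of avoided disease costs) and yields 0.0032
extra QALYs (~1.2 days in full health, almost entirely from the
mental-wellbeing gain during the 12 months the completers stay more
active), for £20,969 per QALY — just above the £20,000 benchmark, so the
decision is knife-edge and the sensitivity analyses matter. The same
pipeline is scripted in `analysis/01_base_case.py` …
`analysis/04_cohort_recovery.py`, which write their tables under
`results/`. A `pacea` command-line interface exposes the stages
(`pacea base-case`, `owsa`, `threshold`, `psa`, `ceac`, `synth`).

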