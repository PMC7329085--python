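# lynchcea

A decision-analytic cost-effectiveness model for **Lynch syndrome (LS)
diagnostic screening** from the perspective of the Italian National Health
Service. The package is aimed at health-economics researchers and public
health analysts who want a transparent, scriptable re-implementation of the
standard "decision tree + Markov cohort" evaluation of universal and
age-targeted LS testing in newly diagnosed colorectal cancer (CRC) patients.

## The model

Three diagnostic strategies are compared against no screening on the annual
cohort of incident CRC probands:

* **Strategy 1** — germline sequencing of all four MMR genes (*MLH1*,
  *MSH2*, *MSH6*, *PMS2*) for every consenting proband;
* **Strategy 2** — tumor immunohistochemistry (IHC) for the MMR proteins;
  MLH1-absent tumors are triaged by methylation-specific MLPA (promoter
  methylation ⇒ sporadic), remaining screen-positives get targeted
  sequencing;
* **Strategy 3** — as Strategy 2 below age 70; probands ≥ 70 are first
  gated on the revised Bethesda criteria.

Probands with a confirmed variant unlock **cascade predictive testing** of
first-degree relatives (FDRs). Detected carrier relatives enter an intensive
prevention programme (2-yearly colonoscopy from 25, daily aspirin, annual
gynecologic surveillance from 35, optional prophylactic surgery at 45);
undetected carriers follow standard relative surveillance (colonoscopy every
5 years from 45). Lifetime costs and quality-adjusted life years (QALYs) per
carrier are computed by a discrete-time Markov cohort model over the states

```
well → CRC(stage 1–4, 5 tunnel years) → second cancer → alive after cancer → death
     → endometrial cancer (5 tunnel years) ↗
```

with annual cycles, a 5-year cure rule, stage-dependent CRC mortality, and
3.5 %/year discounting of costs and benefits. Strategies are compared by the
incremental cost-effectiveness ratio

ICER = ΔC / ΔE  (EUR per QALY gained),

reported against no screening and sequentially along the efficiency
frontier, with net monetary benefit NMB = λ·E − C at a willingness-to-pay
threshold of λ = €30,000/QALY. Uncertainty is handled by one-way (tornado)
analysis and a 1,000-iteration probabilistic sensitivity analysis (beta
distributions for probabilities and utilities, gamma for costs, Dirichlet
for compositional vectors), summarised as cost-effectiveness acceptability
curves.

**Parameter provenance matters here.** Values printed in the underlying
study (uptake 84.8 %/38.9 %, LS share 2.81 %, cumulative CRC risk 38 %/31 %
to age 70, stage distributions, discount rate, …) ship as defaults tagged
`printed`. Values that live only in that study's supplementary material
(unit costs, IHC/MLPA/Bethesda operating characteristics, family size, stage
survival, …) ship as clearly flagged `supplementary_placeholder` defaults —
plausible, overridable, and reported with a warning in every run. Absolute
cost/QALY totals therefore depend on your configuration; the ICER and
frontier arithmetic, the screening-cohort arithmetic and the engine
invariants do not.

## Worked example

```python
from lynchcea import default_parameters, run_pipeline

params = default_parameters()          # bundled base-case configuration
result = run_pipeline(params)
print(result.table1().round(2).to_string(index=False))
```

```
    strategy  ls_cases_detected  screening_cost_eur  cost_per_case_detected_eur  cascade_cost_eur
no_screening                  0                0.00                         NaN              0.00
          s3                876          4965178.78                     5663.07          84075.02
          s2                961          7035674.07                     7318.43          92187.53
          s1               1167         10388000.00                     8896.80         111965.03
```

Universal sequencing (s1) finds the most carriers — 1,167 of the 41,552
tested probands, at €10.39 M — while the age-targeted strategy (s3) is the
cheapest per case detected. The ICER layer applied to published per-strategy
cost/QALY totals:

```python
from lynchcea import OutcomeSummary, icer_table
from lynchcea.synthetic import make_fixture_outcomes

cells = make_fixture_outcomes()["base"]
outcomes = [OutcomeSummary(r.strategy, r.cost_eur, r.qaly) for r in cells.itertuples()]
print(icer_table(outcomes).round(2).to_string(index=False))
```

```
    strategy    cost_eur     qaly  icer_vs_reference  icer_sequential label
no_screening  1505199.28  3369.65                NaN              NaN
          s3  8407988.32 10703.39             941.24           941.24
          s2  9880720.30 11526.37            1026.82          1789.51
          s1 18921334.15 13724.50            1681.93          4112.87
```

Every screening strategy costs well under €30,000 per QALY gained relative
to no screening — screening is cost-effective at the Italian reference
threshold — and the sequential ICERs increase along the frontier, so no
strategy is dominated.

The command-line interface mirrors the library:

```bash
lynch-cea run --out results/ --seed 42          # all tables + manifest
lynch-cea screen --out table1.csv               # decision trees only
lynch-cea psa --iterations 1000 --seed 42       # PSA + CEAC
lynch-cea tornado --range 0.2                   # one-way sensitivity
lynch-cea scenario --name no_gyn_monitoring
```

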