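# hbp-bia

A budget-impact model of adopting the 2017 ACC/AHA hypertension guideline —
which lowered the diagnostic cut-off from 140/90 to 130/80 mmHg and the
treatment goal from SBP < 140 to SBP < 120 mmHg — in a middle-income health
system (Colombia is the motivating case), from the healthcare payer's
perspective over a 3-year horizon (2018–2020).

It is written for health-economics and HTA analysts who want a tested,
scriptable version of this class of model: a deterministic two-scenario
cohort cost model, a second-order Monte Carlo probabilistic sensitivity
analysis (PSA), and forecasting-based external validation, with synthetic
substitutes for the national data sources (population projections,
age-specific prevalence, administrative event counts) so everything runs
without restricted data.

## The model

Two scenarios are compared, each year of the horizon:

- **baseline** — hypertension diagnosed at ≥ 140/90 mmHg, treatment goal
  SBP < 140 (standard control, 1.8 tablets/day);
- **new** — diagnosed at ≥ 130/80 mmHg, treatment goal SBP < 120
  (intensive control, 2.8 tablets/day). The patients added by the lower
  cut-off form a *newly classified stratum* with its own (lower)
  treatment-adherence probability.

Per scenario-year, the prevalent pool N is split by the care cascade

```
treated = (N − N_new)·p_physician·p_adherence + N_new·p_physician·p_adherence_new
untreated = N − treated
```

with p_physician = 0.52, p_adherence = 0.45 and p_adherence_new = 0.2.
Expected annual cardiovascular events (AMI, stroke, heart failure, CV
death) are `treated·p_regime + untreated·p_untreated`, with the regime
probabilities taken from the two arms of the SPRINT trial and separately
calibrated untreated probabilities. Costs per year are medication
(tablets/day × USD 0.00556 × 365), diagnostic aids (0.61 panels/year ×
USD 57.91 over the diagnosed pool) and complication management
(year-specific AMI episode costs, USD 3430 per stroke, and per heart
failure case 2.2 decompensation episodes × USD 1990 plus USD 1131 chronic
management). Treated survivors are carried into the next year's prevalent
pool. The **budget impact** is the difference in total medical-care cost,
new − baseline (negative = saving).

The PSA re-runs the model 5000 times, drawing each parameter once per
iteration from its published distribution — beta for probabilities,
Poisson for resource counts, gamma (COP scale) for costs — shared between
the two scenarios within an iteration, and reports the fraction of
iterations in which the new guideline saves money.

## Worked example

The packaged parameter table (`hbp_bia/data/table1_params.yaml`) carries
every published model input, including the published 2018 prevalent-count
anchors (8,675,154 baseline; 13,271,577 new scenario).

```
$ hbp-bia run --out demo --seed 0
horizon budget impact (new - baseline): 10,066,280,512 USD
  2018: 3,091,107,085 USD
  2019: 3,467,163,309 USD
  2020: 3,508,010,118 USD
wrote demo/summary.json

$ hbp-bia psa --out demo --seed 1 --n-iter 500
fraction of cost-saving iterations: 0.000
  2018: 0.000
  2019: 0.000
  2020: 0.000
wrote demo/psa_summary.json
```

Reading the output: a *positive* yearly difference means the lowered
cut-off costs the payer more that year; here the new scenario adds about
USD 3.1 billion in 2018, and no PSA iteration produces a saving. With the
published parameter table taken at face value, the untreated event
probabilities (e.g. 10.4 %/year stroke risk) dominate the cost of both
scenarios, and since the lower cut-off enlarges the untreated pool, the
model prices the new guideline as a net cost — see
`docs/methods.md` for why this diverges from the originally reported
headline savings and what calibration would be needed to close the gap.
The deterministic cohort tables (`costs_*.csv`, `events_*.csv`,
`cohort_*.csv`) and `summary.json` let you trace every number back to the
cascade arithmetic above.

`hbp-bia validate` forecasts administrative event series (simple
exponential smoothing, α = 0.1, 95 % prediction intervals) and exits
non-zero if the model's expected events fall outside the intervals;
`hbp-bia synth` writes the synthetic population, prevalence, and claims
fixtures.

As a library:

```python
from hbp_bia import engine, default_parameters

params = default_parameters()
projection = engine.default_projection(params, seed=0)
base_spec, new_spec = engine.default_scenarios(params)
base = engine.run_scenario(base_spec, params, projection)
new = engine.run_scenario(new_spec, params, projection)
impact = engine.budget_impact(base, new, params.cpi_by_year)
print(impact.summary())
```

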