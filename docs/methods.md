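# Methods

## Model structure and assumptions

The model is a deterministic annual-cycle cohort flow, not a
microsimulation: compartments are people-counts, events are expected
(real-valued) counts, and all uncertainty is handled in the PSA layer.
Key structural assumptions:

- **Care cascade.** Each year the prevalent hypertensive pool is split
  into *treated* (prescribed by a guideline-adherent physician and
  adherent to the prescription) and *untreated* (never prescribed, or
  prescribed but non-adherent — pooled, because both face the untreated
  event probabilities). Under the 130/80 cut-off, the stratum added by
  the lower threshold is sized as the excess of the new-scenario
  prevalents over the established (140/90) prevalents and enters the
  same cascade with its own adherence probability (0.2 instead of 0.45).
- **Events.** Treated patients face the annual probabilities of their
  control regime (standard SBP < 140 or intensive SBP < 120, the SPRINT
  arms); untreated patients face separately calibrated probabilities.
  Per-outcome probabilities are applied independently — no competing
  risks — mirroring the published design. The untreated
  cardiovascular-death probability is absent from the published table;
  the default borrows the standard-control value (0.0043), switchable to
  zero (`untreated_cvdeath_fallback`). Some death probability is needed
  because deaths drive survivor carry-over.
- **Survivor carry-over.** Treated patients who survive the year join
  the next year's prevalent pool on top of the projection-anchored
  prevalence, and the whole pool is re-partitioned (survivors are not
  permanently "treated"). Deaths are attributed to compartments
  proportionally to their size; the published description does not
  specify an attribution.
- **Costs.** Medication (treated only), diagnostic aids (all diagnosed
  prevalents, 0.61 panels/year), complication management (per-episode
  AMI/stroke; HF as decompensation episodes plus one year of chronic
  management — chronic HF costs do not persist into later years). Deaths
  carry no direct cost. AMI episode costs are year-specific as published
  and not deflated again; CPI deflation (3.95 / 4.35 / 3.95 % for
  2018–2020) is applied only when expressing multi-year totals in
  constant 2018 USD (`total_difference_real_usd`).
- **Integer arithmetic.** Compartment counts are integers, rounded
  half-to-even at compartment boundaries with the residual assigned to
  the untreated compartment, so `treated + untreated == hypertensive`
  holds exactly every scenario-year and conservation is testable as an
  identity.

## Parameters

All inputs live in one flat YAML table (`hbp_bia/data/table1_params.yaml`):
26 named rows (cascade probabilities, per-regime annual event
probabilities, resource-use means, unit costs) plus globals (horizon,
CPI by year, 2877 COP/USD, 5000 PSA iterations, 7.2 % baseline
prevalence, and the published 2018 prevalent-count anchors 8,675,154 /
13,271,577). Probabilities carry beta(α, β) priors (α = events,
β = non-events), resource counts Poisson(λ), and costs gamma(shape,
scale) parameterised in COP and converted to USD after sampling — the
printed gamma parameters are only coherent on the peso scale.

Several published rows are internally inconsistent: the physician
prescription probability (0.52 vs beta(29,31) mean 0.483), the
diagnostic-aid frequency (0.61 vs Poisson λ = 1.5), HF decompensation
episodes (2.2 vs λ = 2) and all three gamma cost rows (e.g. chronic HF
USD 1131 vs an implied gamma mean of ≈ USD 106). These rows are shipped
verbatim and resolved at run time by an explicit `reconcile` policy:
deterministic runs use the printed point estimates; the PSA default,
`rescaled_distribution`, shifts each distribution so its mean equals the
printed point estimate while preserving its dispersion structure (beta
keeps α+β; gamma keeps its shape; Poisson sets λ). `point_estimate`
(sample the printed distributions untouched) and `distribution_mean`
(adopt the distribution means as point estimates) are selectable
alternatives, since the original analysis does not state which reading
its deterministic run used.

## Synthetic data

Three generators stand in for the restricted national sources:

- **Population projection** — compound growth (default 34 M adults over
  20, +1.2 %/year, the demographic scale of Colombia in 2018) apportioned
  into decadal age bands by largest-remainder rounding, so band counts
  sum to year totals exactly.
- **Prevalence tables** — an age-increasing risk shape scaled so the
  population-weighted overall prevalence hits the requested targets
  (7.2 % at the old cut-off by default); the new-cut-off table is a
  uniform up-scaling, so it dominates the old one in every age band.
- **Event histories** — linear-trend annual counts with Gaussian noise,
  clipped at zero, per ICD-10 code (I219 AMI, I509 HF, I64 stroke).

These emulate structure (growth, age gradients, noisy trends), not the
actual national values; passing tests on them demonstrates the model's
internal correctness, not agreement with Colombian administrative data.
The headline runs do not depend on the synthetic prevalence at all: they
use the published absolute prevalent counts via the count-override rule,
with later years scaled by the projection's total growth (the published
analysis gives anchors for 2018 only).

## Probabilistic sensitivity analysis

Second-order Monte Carlo, 5000 iterations by default. Each iteration
draws one value per distribution-tagged parameter and runs both scenarios
with the shared draw (common random parameters — independent draws would
inflate the variance of the difference), leaving the regime-specific beta
rows independent of each other as published. Poisson resource draws are
integers used as population means, accepting the published and unusual
choice of a Poisson prior for a mean. Randomness derives from one root
seed via `SeedSequence.spawn`, one substream per iteration, so results
are reproducible and order-independent. The saving fraction is reported
three ways (per year, on the horizon total, and pooled over
scenario-year cells) because the original summary is ambiguous about
pooling.

## Validation machinery

External validation forecasts each administrative series with simple
exponential smoothing (level-only recursion, S₁ = y₁, α = 0.1) and a
95 % prediction interval, `forecast ± 1.96·σ̂`, where σ̂ is the ddof-1
standard deviation of the one-step-ahead residuals, held flat over the
horizon. This is one standard SES interval; the construction is isolated
in `ses_forecast` so an alternative (e.g. variance growing with horizon)
can be swapped in. The recursion is cross-checked against statsmodels'
`SimpleExpSmoothing` in the test suite. Model events are "adequately
predicted" if inside the closed interval. Scenario effect sizes are
summarised as hazard ratios, `ln(1 − r_new)/ln(1 − r_baseline)` on annual
cumulative incidences; reference trial confidence intervals for the HR
check are user-supplied configuration, never hard-coded, because they
belong to an external publication.

## Known limitations

- **The published headline figures are not recoverable from the
  published inputs.** Taking the published parameter table and the 2018
  prevalent counts at face value, the untreated event probabilities
  (0.047 AMI, 0.104 stroke, 0.0396 HF per year — flagged "calibrated" in
  the source) put the baseline complication cost near USD 4.9 billion,
  an order of magnitude above the originally reported USD 466 million,
  and because the lower cut-off enlarges the untreated pool by ~4.1 M
  people, the model prices the new guideline as a net cost
  (+USD 3.1 billion in 2018) rather than the reported USD 108 million
  saving; correspondingly no PSA iteration is cost-saving. Back-solving
  shows the reported figures are also mutually inconsistent under any
  cascade of this family (the 2018 complication cost and 3-year stroke
  burden imply incompatible event pools), so the original calibration
  evidently involved additional, unpublished structure. This package
  deliberately implements the documented structure with the published
  numbers rather than fitting hidden factors to reproduce headline
  outputs; every divergence above is computed, not assumed, by the test
  suite and `scripts/acceptance.py`.
- Sex/age-stratified event probabilities, lifestyle modification,
  quality-of-life outcomes, renal/retinal/peripheral-artery
  complications, rehabilitation and outpatient follow-up costs, and
  adverse events of intensive treatment are out of scope, as in the
  original design.
- Competing risks are ignored; expected events are linear in
  compartments and may jointly exceed plausible per-person risk at
  extreme parameter values.
- Chronic HF costs apply in the incident year only (a persistence hook
  exists but is out of scope).
- Whether costs should be deflated to 2018 or inflated forward is
  ambiguous in the original description; per-year outputs are nominal
  and deflation is opt-in when aggregating.

## Problem sizes

The deterministic 3-year, two-scenario run is a few milliseconds; the
full 5000-iteration PSA completes in well under a minute on one CPU.
Test-suite PSAs use 300–5000 iterations; sampling-convergence checks use
10⁵ draws.
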