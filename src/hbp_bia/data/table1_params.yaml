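# Published input table of the hypertension-guideline budget-impact model
# (point estimates + PSA distributions), reproduced verbatim.
#
# Schema: parameters.<name> = {estimate, units, dist?, params?, dist_scale?, note?}
#   dist in {beta, poisson, gamma, fixed}; params: beta/gamma -> a, b (shape/scale),
#   poisson -> lam, fixed -> value. dist_scale "cop" marks gamma cost priors
#   parameterised in Colombian pesos (converted to USD at globals.fx_cop_per_usd
#   after sampling).
schema_version: 1
globals:
  baseline_prevalence: 0.072
  horizon_years: [2018, 2019, 2020]
  cpi_by_year: {2018: 3.95, 2019: 4.35, 2020: 3.95}
  fx_cop_per_usd: 2877
  psa_iterations: 5000
  prevalent_count_overrides:
    baseline: {2018: 8675154}
    new: {2018: 13271577}
parameters:
  physician_prescription:
    estimate: 0.52
    units: probability
    dist: beta
    params: {a: 29, b: 31}
    note: physicians prescribing per guideline
  adherence_standard:
    estimate: 0.45
    units: probability
    dist: beta
    params: {a: 45, b: 55}
    note: patient adherence, established hypertensives (BP > 140/90)
  adherence_new_stratum:
    estimate: 0.2
    units: probability
    dist: beta
    params: {a: 20, b: 80}
    note: patient adherence, newly classified stratum (SBP 130-139 / DBP 80-89)
  ami_standard:
    estimate: 0.0078
    units: probability_per_year
    dist: beta
    params: {a: 116, b: 4562}
    note: annual AMI probability, standard control (BP < 140/90)
  stroke_standard:
    estimate: 0.0047
    units: probability_per_year
    dist: beta
    params: {a: 140, b: 4543}
    note: annual stroke probability, standard control
  hf_standard:
    estimate: 0.0067
    units: probability_per_year
    dist: beta
    params: {a: 100, b: 4583}
    note: annual heart-failure probability, standard control
  cvdeath_standard:
    estimate: 0.0043
    units: probability_per_year
    dist: beta
    params: {a: 65, b: 4618}
    note: annual cardiovascular-death probability, standard control
  ami_intensive:
    estimate: 0.0065
    units: probability_per_year
    dist: beta
    params: {a: 97, b: 4586}
    note: annual AMI probability, intensive control (BP < 120/80)
  stroke_intensive:
    estimate: 0.0041
    units: probability_per_year
    dist: beta
    params: {a: 62, b: 4616}
    note: annual stroke probability, intensive control
  hf_intensive:
    estimate: 0.0041
    units: probability_per_year
    dist: beta
    params: {a: 62, b: 4616}
    note: annual heart-failure probability, intensive control
  cvdeath_intensive:
    estimate: 0.0025
    units: probability_per_year
    dist: beta
    params: {a: 37, b: 4641}
    note: annual cardiovascular-death probability, intensive control
  ami_untreated:
    estimate: 0.047
    units: probability_per_year
    dist: beta
    params: {a: 47, b: 953}
    note: annual AMI probability, untreated patients (calibrated)
  stroke_untreated:
    estimate: 0.1040
    units: probability_per_year
    dist: beta
    params: {a: 104, b: 896}
    note: annual stroke probability, untreated patients (calibrated)
  hf_untreated:
    estimate: 0.0396
    units: probability_per_year
    dist: beta
    params: {a: 39, b: 961}
    note: annual heart-failure probability, untreated patients (calibrated)
  tablets_per_day_intensive:
    estimate: 2.8
    units: tablets_per_day
    dist: poisson
    params: {lam: 2.8}
    note: mean daily tablets, intensive control
  tablets_per_day_standard:
    estimate: 1.8
    units: tablets_per_day
    dist: poisson
    params: {lam: 1.8}
    note: mean daily tablets, standard control
  diagnostic_aid_frequency:
    estimate: 0.61
    units: prescriptions_per_year
    dist: poisson
    params: {lam: 1.5}
    note: mean annual prescriptions of the diagnostic-aid panel
  hf_decompensation_episodes:
    estimate: 2.2
    units: episodes_per_year
    dist: poisson
    params: {lam: 2}
    note: mean annual decompensation episodes per heart-failure case
  medication_cost_per_tablet_day:
    estimate: 0.00556
    units: usd_per_tablet_day
    note: weighted average daily cost of antihypertensive medication
  diagnostic_aids_cost:
    estimate: 57.91
    units: usd
    note: average total cost of the diagnostic-aid panel (currency unlabeled
      in the source; treated as USD consistently with neighbouring rows)
  ami_episode_cost_2018:
    estimate: 2938
    units: usd_per_episode
    note: average total cost per AMI episode, 2018 (no variance data)
  ami_episode_cost_2019:
    estimate: 3235
    units: usd_per_episode
    note: average total cost per AMI episode, 2019
  ami_episode_cost_2020:
    estimate: 2934
    units: usd_per_episode
    note: average total cost per AMI episode, 2020
  stroke_episode_cost:
    estimate: 3430
    units: usd_per_episode
    dist: gamma
    params: {a: 0.44604, b: 19360084}
    dist_scale: cop
    note: average total cost per stroke episode
  hf_decompensation_cost:
    estimate: 1990
    units: usd_per_episode
    dist: gamma
    params: {a: 0.44248, b: 14526853}
    dist_scale: cop
    note: average total cost per decompensated heart-failure episode
  hf_chronic_cost:
    estimate: 1131
    units: usd_per_year
    dist: gamma
    params: {a: 0.1599, b: 1902392}
    dist_scale: cop
    note: average total cost of chronic heart-failure outpatient management
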