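# Default run configuration.  Every value can be overridden by a user YAML;
# unknown keys are rejected.  Monetary values are EUR 2022.
seed: 0
output_dir: results
scenario: BC
perspective: societal
n_psa_iterations: 10000
wtp_grid: [0, 5000, 10000, 20000, 30000, 40000, 50000, 60000, 80000, 100000]
wtp: 50000

cohort:
  n_patients: 670
  lead_median: 0.31
  lead_iqr: [0.22, 0.45]
  tertile_boundaries: null        # null -> theoretical tertiles (upper ~0.38)
  max_followup: 10.0
  # synthetic generator truth (lognormal meanlog/sdlog per lead tertile;
  # gamma shape/rate for the death endpoints)
  gf_params_per_group:
    low: [4.2, 1.8]
    medium: [3.8, 1.8]
    high: [3.0, 1.8]
  dwfg_params: [1.1, 0.04]
  dwgf_params: [1.0, 0.15]

# Optional bypass: externally estimated survival parameters (endpoint ->
# family/params/ci).  When present, the fitting stage is skipped and these
# are used directly.
survival_params: null

survival_overrides:               # expert-informed family selection
  GF: lognormal
  DWFG: gamma
  DwGF: gamma

model:
  horizon: 40
  cohort_size: 10000
  baseline_age: 53.0
  p_retransplant_base: 0.15
  age_decline_start: 65.0
  age_decline_zero: 80.0
  p_primary_nonfunction: 0.007
  group_mix:
    low: 0.3333333333333333
    medium: 0.3333333333333333
    high: 0.3333333333333334

costs:
  gf_initial: 2818.80
  dialysis_chd: 113142.50
  dialysis_hhd: 106344.10
  dialysis_apd: 109863.60
  dialysis_capd: 94756.94
  modality_mix: [0.80, 0.04, 0.08, 0.08]
  transplantation: 103993.68
  transplant_upkeep_annual: 14376.98
  death_oneoff: 1392.03

utilities:
  u_fg: 0.81
  u_hd: 0.56
  u_pd: 0.58
  hd_share: 0.84
  pd_share: 0.16

productivity:
  work_posttx: [0.57, 0.41, 0.061]
  work_dialysis: [0.32, 0.19, 0.028]
  hospital_days_living: 13.30
  hospital_days_deceased: 7.80
  living_donor_share: 0.50
  friction_days: 85.0
  hours_per_day: 8.0
  wage_male: 28.45
  wage_female: 24.70
  male_fraction: 0.60
  retirement_age: 65.0

discounting:
  costs: 0.04
  effects: 0.015

intervention_costing:
  blood_draw: 15.00
  lead_lab: 50.63
  iron_lab: 26.39
  ast_alt_lab: 5.38
  dmsa_course: 570.95
  iron_supplement: 46.48
  supplement_unit_weeks: 8.0

population:
  prevalence: 12068
  incidence: 957
  horizon: 5
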