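# Base-case inputs for the phosphate-binder sequencing cost-effectiveness
# model. Euros, 2013 value; serum phosphorus (SP) in mg/dL; annual
# probabilities as fractions.
#
# Pack prices already include the 7.5% mandatory Spanish rebate
# (settings.rebate_applied: true). Daily doses are chosen so that
# dose x cost-per-gram x 365 reproduces the catalogue annual treatment
# costs (LC 1702/2042, CC 30/50, CA 68/136, CB average 49/93 EUR/year);
# the clinical dose recommendations (CC 3,000/1,500, CA 5,000/3,000
# mg/day) are not compatible with those annual costs and are recorded in
# docs/methods.md. CA carries a cost-per-gram override because its
# catalogue EUR/g (0.124) is not reproducible from its pack price
# (7.13 / 75 g = 0.095); the annual costs follow the catalogue value.
drugs:
  lc:
    name: lanthanum carbonate
    mg_per_tablet: 750
    tablets_per_pack: 90
    pack_price: 167.86
    daily_dose_predialysis: 1875
    daily_dose_dialysis: 2250
  cc:
    name: calcium carbonate
    mg_per_tablet: 1250
    tablets_per_pack: 60
    pack_price: 2.09
    daily_dose_predialysis: 3000
    daily_dose_dialysis: 5000
  ca:
    name: calcium acetate
    mg_per_tablet: 1250
    tablets_per_pack: 60
    pack_price: 7.13
    cost_per_gram_override: 0.124
    daily_dose_predialysis: 1500
    daily_dose_dialysis: 3000

efficacy:
  response_rate_cb_predialysis: {value: 0.445, ci: [0.321, 0.571]}
  response_rate_cb_dialysis: {value: 0.341, ci: [0.310, 0.374]}
  response_rate_lc_predialysis: {value: 0.383, ci: [0.327, 0.440]}
  response_rate_lc_dialysis: {value: 0.166, ci: [0.135, 0.199]}
  # trial arm sizes backing the response rates (binomial PSA sampling)
  n_trial_cb_pre: 28
  n_trial_lc_pre: 56
  n_trial_cb_dial: 123
  n_trial_lc_dial: 257

epidemiology:
  mortality_predialysis_annual: 0.123
  # Baseline annual dialysis mortality is not published for this cohort;
  # the value below was calibrated (scripts/calibrate_dialysis_mortality.py)
  # so that the continued-CB strategy yields ~6.868 discounted life years
  # per patient over the 40-year horizon.
  mortality_dialysis_annual: 0.044051
  mortality_dialysis_sd: 0.0044051  # PSA: normal, 10% of mean (no CI published)
  progression_annual: {value: 0.143, ci: [0.136, 0.150]}
  rr_progression_per_mgdl: {value: 1.19, ci: [1.10, 1.29]}
  # representative SP per response status (no SP trajectory is tracked)
  sp_responder: 4.0
  sp_nonresponder_predialysis: 5.7   # trial baseline mean, predialysis
  sp_nonresponder_dialysis: 6.0      # dialysis trials randomized above 5.58

# SP band rows: [low, high (null = open), RR, ci_low, ci_high];
# bands are lower-inclusive / upper-exclusive.
rr_tables:
  predialysis:
    - [0.0, 2.5, 0.95, 0.69, 1.32]
    - [2.5, 3.0, 1.00, 1.00, 1.00]
    - [3.0, 3.5, 1.15, 0.95, 1.39]
    - [3.5, 4.0, 1.32, 1.09, 1.61]
    - [4.0, 4.5, 1.34, 1.05, 1.71]
    - [4.5, 5.0, 1.83, 1.33, 2.51]
    - [5.0, 5.5, 1.90, 1.30, 2.79]
    # the published CI for the bands above 5.5 (1.10-1.29) does not
    # bracket the point estimate; the PSA falls back to sd = 10% of mean
    - [5.5, 6.0, 1.90, 1.10, 1.29]
    - [6.0, 7.0, 1.90, 1.10, 1.29]
    - [7.0, 8.0, 1.90, 1.10, 1.29]
    - [8.0, 9.0, 1.90, 1.10, 1.29]
    - [9.0, null, 1.90, 1.10, 1.29]
  dialysis:
    - [0.0, 2.5, 1.00, 0.96, 1.24]
    - [2.5, 3.0, 1.00, 0.96, 1.24]
    - [3.0, 3.5, 1.00, 0.93, 1.07]
    - [3.5, 4.0, 1.00, 0.93, 1.07]
    - [4.0, 4.5, 1.00, 1.00, 1.00]
    - [4.5, 5.0, 1.00, 1.00, 1.00]
    - [5.0, 5.5, 1.07, 1.01, 1.14]
    - [5.5, 6.0, 1.07, 1.01, 1.14]
    - [6.0, 7.0, 1.25, 1.17, 1.34]
    - [7.0, 8.0, 1.43, 1.31, 1.54]
    - [8.0, 9.0, 1.67, 1.51, 1.86]
    - [9.0, null, 2.02, 1.76, 2.27]
  # alternative dialysis mortality-risk set (scenario analysis only);
  # its published bands 5.5-6.5 and 6.6-7.8 are snapped to the 5.5-6.5 /
  # 6.5-8.0 tiling used here
  dialysis_alt:
    - [0.0, 4.5, 1.00, 0.87, 1.15]
    - [4.5, 5.5, 1.00, 1.00, 1.00]
    - [5.5, 6.5, 1.02, 0.89, 1.17]
    - [6.5, 8.0, 1.18, 1.02, 1.36]
    - [8.0, 9.0, 1.39, 1.21, 1.60]
    - [9.0, null, 1.39, 1.21, 1.60]

utilities:
  utility_predialysis: 0.71
  utility_dialysis: 0.61
  vomit_decrement: 0.04082      # per vomiting episode
  vomit_rate_lc_predialysis: 0.04   # episodes/year on LC
  vomit_rate_lc_dialysis: 0.072
  utility_sd: 0.05              # PSA beta sampling (no CI published)

settings:
  cohort_size: 1000
  horizon_years: 40
  discount_rate: 0.03
  days_per_year: 365
  threshold_lambda: 30000
  sp_target: 4.6
  sp_target_dialysis: null      # defaults to sp_target
  sp_initiation_predialysis: 4.6
  sp_initiation_dialysis: 5.5
  future_dialysis_cost_mode: attributable_only
  dialysis_annual_cost: 42555.6
  rebate_fraction: 0.075
  rebate_applied: true
  lc_trial_weeks: 8
  seed: 12345
  rr_application: rate_domain
  competing_risk: death_first
  discount_timing: half_cycle
  re_evaluate_on_dialysis: true
  cost_cv: 0.2                  # PSA lognormal dispersion for costs

cb_composition: average
use_alt_dialysis_rr: false
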