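# Base-case inputs for the early vs deferred endovenous ablation
# cost-effectiveness model. Monetary values are 2021 USD (Medicare national
# average payments); probabilities are per monthly cycle. Segment intervals
# are half-open [start, end) in months; end: null means open-ended.

transitions:
  mortality: 0.001           # all-cause, age 65+, per month; both arms, all alive states
  early:
    healing:
      - {start: 1,  end: 6,    p: 0.133}
      - {start: 6,  end: 12,   p: 0.090}
      - {start: 12, end: null, p: 0.045}
    recurrence:
      - {start: 1,  end: 12,   p: 0.011}
      - {start: 12, end: 24,   p: 0.004}
      - {start: 24, end: null, p: 0.007}
  deferred:
    healing:
      - {start: 1,  end: 6,    p: 0.119}
      - {start: 6,  end: 12,   p: 0.065}
      - {start: 12, end: null, p: 0.032}
    recurrence:
      - {start: 1,  end: 12,   p: 0.016}
      - {start: 12, end: 24,   p: 0.005}
      - {start: 24, end: null, p: 0.007}

costs:
  unit_costs:
    # one-time endovenous ablation procedure (primary vein + multi-vein add-on)
    ablation_mechanochemical:        {code: "36473",  base: 1448}
    ablation_mechanochemical_addon:  {code: "36474",  base: 296}
    ablation_radiofrequency:         {code: "36475",  base: 1323}
    ablation_radiofrequency_addon:   {code: "36476",  base: 314}
    ablation_laser:                  {code: "36478",  base: 1215}
    ablation_laser_addon:            {code: "36479",  base: 138}
    # initial outpatient visit, charged once to the entering cohort
    initial_eval_physician:          {code: "99203",  base: 85}
    initial_debridement_physician:   {code: "11042",  base: 63}
    initial_visit_facility:          {code: "99213",  base: 86}
    initial_debridement_facility:    {code: "11042",  base: 220}
    # recurring weekly outpatient visits (physician + facility components);
    # CMS does not allow compression billing when debridement is performed
    visit_debridement_physician:     {code: "97597",  base: 36}
    visit_debridement_facility:      {code: "97597",  base: 114}
    visit_compression_physician:     {code: "99212",  base: 36}
    visit_compression_facility:      {code: "29581",  base: 83}
    # home health, 60-day episode payment
    home_health_episode:             {code: "C2F2S1", base: 2808}
    # compression stockings per pair, 6-month supply (healed state)
    stockings_6mo:                   {code: "A6532",  base: 72}
    # hospitalization (DRG payments)
    hosp_debridement_complication:   {code: "DRG571", base: 10832}
    hosp_ulcer_complication:         {code: "DRG593", base: 8882}
    hosp_cellulitis_major:           {code: "DRG602", base: 9872}
    hosp_cellulitis_no_major:        {code: "DRG603", base: 5562}
    # pain medication, monthly prescription cost
    pain_amitriptyline:              {code: null,     base: 43}
    pain_gabapentin:                 {code: null,     base: 124}
    pain_hydrocodone:                {code: null,     base: 22}
  ablation_mix: {mechanochemical: 0.40, radiofrequency: 0.40, laser: 0.20}
  multi_vein_fraction: 0.10
  visits_per_month: 4.333333333333333   # 1 visit/week, 52/12 per month
  debride_prob_per_visit: 0.125
  debride_window_months: 3              # debridement only in the first 3 months
  home_health_fraction: 0.25            # fraction with weekly home-health visits
  home_health_episode_months: 2.0       # 60-day episode prorated monthly
  hosp_monthly_probs:
    ulcer: 0.0083                       # skin debridement/ulcer with complications
    cellulitis_major: 0.0008
    cellulitis_no_major: 0.0033
  ulcer_drg_weights:                    # split of the pooled ulcer probability
    hosp_debridement_complication: 0.5
    hosp_ulcer_complication: 0.5
  pain_med_mix: {amitriptyline: 0.40, gabapentin: 0.10, hydrocodone: 0.50}
  include_initial_visit: true

utilities:
  unhealed: 0.69
  healed: 0.75
  dead: 0.0
  # multiplicative aging disutility for a 65+ cohort, calibrated once with
  # scripts/calibrate_age_adjustment.py and frozen here
  age_adjustment: 0.970706

settings:
  horizon_months: 36
  cycle_length_months: 1
  annual_discount_rate: 0.03
  wtp: 100000
  psa_iterations: 10000
  seed: 20221221
  range_fraction: 0.20
  half_cycle_correction: false
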