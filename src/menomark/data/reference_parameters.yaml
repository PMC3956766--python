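# Reference parameterisation of the menorrhagia treatment-pathway model.
# Costs in GBP at 2011 prices (UK NHS perspective); utilities are annual
# health-state weights from the EQ-5D-3L and SF-6D instruments; transition
# counts are observed month-to-month moves (Dirichlet concentrations for
# probabilistic sensitivity analysis).
#
# State template (shared by both arms; "other" = the non-allocated
# treatment): initial, well_allocated, symptomatic, change_to_other,
# well_with_other, no_treatment, surgery, post_surgery.

meta:
  currency: GBP
  price_year: 2011
  description: >
    Two-arm monthly-cycle Markov cohort model of LNG-IUS versus usual
    medical treatment for heavy menstrual bleeding, 24-month horizon.

settings:
  horizon_cycles: 24
  discount_rate_annual: 0.035
  discount_convention: smooth
  entry_month_accrual: true
  initial_row_cycles: 1
  coincident_rule: subsequent

costs:
  staff:
    gp_10min: 26.67
    gp_20min: 53.33
    nurse_10min: 8.50
    nurse_20min: 17.00
  lng_ius:
    consultation: 26.67            # GP, 10 minutes
    insertion:
      gp_20min: 53.33
      nurse_20min: 17.00
      device: 88.00
      sterile_pack: 21.63
    discontinuation:
      gp_10min: 26.67
      nurse_10min: 8.50
      sterile_pack_removal: 3.77
    reviews:
      - {cycle: 1, cost: 26.67, label: six_week_review}    # ~6 weeks, GP 10 min
      - {cycle: 3, cost: 26.67, label: three_month_review}
  usual_medical:
    consultation: 26.67            # GP, 10 minutes
    discontinuation:
      gp_10min: 26.67
    reviews:
      - {cycle: 3, cost: 26.67, label: three_month_review}
    # BNF pack prices; packs cover roughly a 3-month supply at trial dosing
    # (Cerazette 3x28, Microgynon 3x63, Depo-Provera 12-weekly).  Weighted
    # equally: the prescribing mix behind the published weighted average is
    # not recoverable.
    drugs:
      progestogen_cerazette: 8.68
      tranexamic_acid: 14.30
      mefenamic_acid: 15.72
      norethisterone: 2.18
      combined_oc_microgynon: 2.82
      depot_injection: 6.01
    drug_weights: equal
    months_per_pack: 3
  prescription_timing: start       # dispensed for the month ahead
  surgery: 1720.18                 # weighted ablation/hysterectomy cost

utilities:
  eq5d:
    lng_ius:
      initial:          {value: 0.756, beta: [653, 211]}
      # Printed value 0.98 is inconsistent with its own Beta(1169, 297)
      # (mean 0.797) and with the published QALY totals; the Beta mean is
      # used deterministically.
      well_allocated:   {value: 0.98, beta: [1169, 297], use_beta_mean: true}
      symptomatic:      {value: 0.744, beta: [130, 45]}
      change_to_other:  {value: 0.817, beta: [20, 5]}
      well_with_other:  {value: 0.714, beta: [66, 26]}
      no_treatment:     {value: 0.785, beta: [70, 19]}
      surgery:          {value: 0.620, linked_to: post_surgery}
      post_surgery:     {value: 0.827, beta: [59, 12]}
    usual_medical:
      initial:          {value: 0.714, beta: [514, 206]}
      well_allocated:   {value: 0.728, beta: [528, 197]}
      symptomatic:      {value: 0.756, beta: [311, 100]}
      change_to_other:  {value: 0.694, beta: [49, 21]}
      well_with_other:  {value: 0.801, beta: [282, 70]}
      no_treatment:     {value: 0.766, beta: [223, 68]}
      surgery:          {value: 0.619, linked_to: post_surgery}
      post_surgery:     {value: 0.825, beta: [64, 14]}
  sf6d:
    lng_ius:
      initial:          {value: 0.597, beta: [10204, 6883]}
      well_allocated:   {value: 0.598, beta: [17912, 12061]}
      symptomatic:      {value: 0.589, beta: [3464, 2418]}
      change_to_other:  {value: 0.596, beta: [1066, 723]}
      well_with_other:  {value: 0.594, beta: [2032, 1390]}
      no_treatment:     {value: 0.604, beta: [2108, 1380]}
      surgery:          {value: 0.430, linked_to: post_surgery}
      post_surgery:     {value: 0.574, beta: [330, 245]}
    usual_medical:
      initial:          {value: 0.603, beta: [9892, 6519]}
      well_allocated:   {value: 0.592, beta: [9664, 6647]}
      symptomatic:      {value: 0.606, beta: [5168, 3359]}
      change_to_other:  {value: 0.627, beta: [2494, 1484]}
      well_with_other:  {value: 0.595, beta: [4069, 2766]}
      no_treatment:     {value: 0.586, beta: [3548, 2509]}
      surgery:          {value: 0.454, linked_to: post_surgery}
      post_surgery:     {value: 0.606, beta: [2136, 1391]}

transitions:
  lng_ius:
    first_cycle:
      counts: {well_allocated: 182, symptomatic: 72, change_to_other: 19, no_treatment: 12}
    rows:
      well_allocated: {fixed: {well_allocated: 1.0}}
      symptomatic:
        counts: {symptomatic: 700, change_to_other: 27, no_treatment: 32, surgery: 13}
      change_to_other:
        counts: {change_to_other: 109, well_with_other: 32, no_treatment: 7, surgery: 6}
      well_with_other: {fixed: {well_with_other: 1.0}}
      # Printed probabilities and counts disagree for this row; the printed
      # vector is used deterministically, the counts in PSA.
      no_treatment:
        counts: {change_to_other: 1, no_treatment: 540, surgery: 10}
        printed: {change_to_other: 0.0, no_treatment: 0.984, surgery: 0.016}
      surgery: {fixed: {post_surgery: 1.0}}
      post_surgery: {fixed: {post_surgery: 1.0}}
  usual_medical:
    first_cycle:
      counts: {well_allocated: 115, symptomatic: 162, change_to_other: 2, no_treatment: 7}
    rows:
      well_allocated: {fixed: {well_allocated: 1.0}}
      symptomatic:
        counts: {symptomatic: 1474, change_to_other: 80, no_treatment: 65, surgery: 17}
      change_to_other:
        counts: {change_to_other: 120, well_with_other: 62, no_treatment: 9, surgery: 8}
      well_with_other: {fixed: {well_with_other: 1.0}}
      no_treatment:
        counts: {change_to_other: 1, no_treatment: 846, surgery: 6}
      surgery: {fixed: {post_surgery: 1.0}}
      post_surgery: {fixed: {post_surgery: 1.0}}
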