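# Base-case model inputs for the first-line LY01008 + carboplatin/paclitaxel
# vs chemotherapy-alone comparison in advanced/recurrent nonsquamous NSCLC
# (Chinese healthcare-system perspective, 2020 USD).
#
# Each entry under `parameters` carries the base value, the one-way DSA
# range (95% CI for hazard ratios and utilities, 0-8% for the discount
# rate, +/-50% of baseline otherwise) and the PSA distribution family.
# `dist: fixed` marks parameters excluded from both DSA and PSA.

structural:
  cycle_days: 21
  horizon_years: 30
  wtp_per_qaly_usd: 33438.0          # 3x China's 2020 per-capita GDP
  fx_cny_per_usd: 6.8974
  max_chemo_cycles: 6                # carboplatin/paclitaxel induction cycles
  p_subsequent_therapy: 1.0          # PD patients on subsequent therapy (vs BSC)
  carboplatin_target_auc: 6.0
  half_cycle_correction: false
  billing: linear-mg
  effectiveness_measure: life-years  # reproduces the published analysis
  ly01008_dose_mg_per_kg: 15.0
  ly01008_dose_multiplier: 1.0       # 0.5 = real-world 7.5 mg/kg scenario

parameters:
  weibull_os_scale:    {value: 0.004716, dist: fixed}
  weibull_os_shape:    {value: 1.533854, dist: fixed}
  weibull_pfs_scale:   {value: 0.003867, dist: fixed}
  weibull_pfs_shape:   {value: 2.335407, dist: fixed}
  hr_os:               {value: 0.654, low: 0.302, high: 1.410, dist: normal}
  hr_pfs:              {value: 0.405, low: 0.078, high: 2.160, dist: normal}
  p_discontinue_combo: {value: 0.004298, low: 0.002149, high: 0.006448, dist: beta}
  p_discontinue_chemo: {value: 0.006372, low: 0.003186, high: 0.009558, dist: beta}
  ly01008_price:       {value: 24.99, low: 12.49, high: 37.48, dist: gamma}   # per 15 mg
  paclitaxel_price:    {value: 57.51, low: 28.75, high: 86.26, dist: gamma}   # per 175 mg
  carboplatin_price:   {value: 1.37, low: 0.69, high: 2.06, dist: gamma}      # per 6 mg
  nivolumab_price:     {value: 60.35, low: 30.18, high: 90.53, dist: gamma}   # per 4.5 mg
  followup_cost:       {value: 55.60, low: 27.80, high: 83.40, dist: gamma}   # per cycle
  subsequent_cost:     {value: 854.05, low: 427.02, high: 1281.08, dist: gamma}
  bsc_cost:            {value: 337.50, low: 168.75, high: 506.25, dist: gamma}
  palliative_cost:     {value: 2627.80, low: 1313.90, high: 3941.70, dist: gamma}
  ae_cost_combo:       {value: 1025.82, low: 512.91, high: 1538.73, dist: gamma}
  ae_cost_chemo:       {value: 745.01, low: 372.51, high: 1117.52, dist: gamma}
  u_pfs:               {value: 0.856, low: 0.718, high: 0.994, dist: beta}
  u_pd:                {value: 0.768, low: 0.595, high: 0.941, dist: beta}
  disutility_combo:    {value: 0.061, low: 0.031, high: 0.092, dist: beta}
  disutility_chemo:    {value: 0.080, low: 0.040, high: 0.119, dist: beta}
  discount_rate:       {value: 0.05, low: 0.0, high: 0.08, dist: fixed}  # varied in DSA only
  weight:              {value: 65.0, low: 32.5, high: 97.5, dist: normal}    # kg
  bsa:                 {value: 1.72, low: 0.86, high: 2.58, dist: normal}    # m^2
  crcl:                {value: 70.0, low: 35.0, high: 105.0, dist: normal}   # ml/min
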