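# Default pharmacological constants for the three decanoate-based long-acting
# injectable dopamine antagonists (LIDAs) shipped with lidataper.
#
# Sources of each number (published pharmacokinetic and [11C]-raclopride
# neuroimaging literature for these drugs):
#   half_life_days     apparent elimination half-life of the decanoate depot
#   tmax_days          time from injection to the single-dose plasma peak
#   emax_percent       maximal striatal D2 occupancy (imaging studies assume 100)
#   ec50_ng_ml         plasma level giving half-maximal occupancy
#                      (zuclopenthixol: 2.887 nmol/L x 400.965 g/mol = 1.158 ng/ml)
#   depot_anchor       a published steady-state peak (Css,max) at the maximum
#                      licensed regimen, used to calibrate the depot scale
#   oral_slope_ng_ml_per_mg
#                      plasma level per mg/day of the oral form (linear):
#                      haloperidol 10 mg -> 28.22 nmol/l = 10.61 ng/ml (1.061)
#                      zuclopenthixol 20 mg -> 13 ng/ml (0.65)
#                      flupentixol 1.5 mg -> 0.495 ng/ml peak (0.33); the
#                      trough-based alternative (1 mg -> 0.2 ng/ml) is kept
#                      under oral_slope_alternatives.
#   depot_increments   practical dosing grid: 0.2 ml of the lowest-strength
#                      ampoule currently marketed, as mg bands
#   oral_increment_mg  smallest practical oral step (tablet/liquid)

flupentixol:
  half_life_days: 17.0
  tmax_days: 7.0
  emax_percent: 100.0
  ec50_ng_ml: 0.68
  molar_mass_g_mol: 434.52
  depot_anchor: {dose_mg: 400.0, interval_days: 7.0, css_max_ng_ml: 102.61}
  oral_slope_ng_ml_per_mg: 0.33
  oral_slope_alternatives: {trough: 0.2}
  depot_increments:
    - {upper_dose_mg: 60.0, increment_mg: 4.0}
    - {upper_dose_mg: .inf, increment_mg: 20.0}
  oral_increment_mg: 0.5
  max_licensed: {dose_mg: 400.0, interval_days: 7.0}

haloperidol:
  half_life_days: 20.0
  tmax_days: 7.0
  emax_percent: 100.0
  ec50_ng_ml: 0.51
  molar_mass_g_mol: 375.9
  depot_anchor: {dose_mg: 300.0, interval_days: 28.0, css_max_ng_ml: 9.65}
  oral_slope_ng_ml_per_mg: 1.061
  depot_increments:
    - {upper_dose_mg: 150.0, increment_mg: 10.0}
    - {upper_dose_mg: .inf, increment_mg: 20.0}
  oral_increment_mg: 0.5
  max_licensed: {dose_mg: 300.0, interval_days: 28.0}

zuclopenthixol:
  half_life_days: 19.0
  tmax_days: 7.0
  emax_percent: 100.0
  ec50_ng_ml: 1.158
  molar_mass_g_mol: 400.965
  depot_anchor: {dose_mg: 600.0, interval_days: 7.0, css_max_ng_ml: 45.73}
  oral_slope_ng_ml_per_mg: 0.65
  depot_increments:
    - {upper_dose_mg: .inf, increment_mg: 40.0}
  oral_increment_mg: 1.0
  max_licensed: {dose_mg: 600.0, interval_days: 7.0}
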