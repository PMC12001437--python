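# Published validation-cohort summary statistics (the printed inputs the
# reproduce-paper command works from).  432 urine samples: 108 urothelial
# cancer (UC), 191 non-neoplastic urinary-tract disorders, 76 benign
# lesions, 57 other cancers; three-marker (VIM/TMEM220/PPM1N) parallel
# OR-rule model at Ct < 45.
positive_group: UC
group_sizes:
  UC: 108
  non_neoplastic: 191
  benign: 76
  other_cancer: 57
# model true positives among UC (the published marker-overlap counts use
# 102 as their denominator)
tp: 102
# printed per-group specificities (fractions)
specificity_rates:
  non_neoplastic: 0.9634
  benign: 0.9076
  other_cancer: 0.8772
# printed headline metrics, percent (for the comparison table only)
printed_percent:
  sensitivity: 94.44
  specificity_overall: 93.52
  ppv: 82.93
  npv: 98.06
# single-marker worked example: VIM
vim:
  tp: 83          # of 108 UC -> sensitivity 76.85%
  correct: 401    # of 432    -> accuracy 92.82%
# stage-stratified sensitivities as printed: percentage plus exact 95% CI
stage_strata:
  "0a/0is": {percent: "80.00", ci: ["44.39", "97.48"]}
  "I":      {percent: "88.57", ci: ["73.26", "96.8"]}
  "II":     {percent: "100",   ci: ["83.89", "100"]}
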