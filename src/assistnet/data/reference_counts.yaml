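# Published summary counts of the motivating help-seeking youth cohort
# (N = 1107, five primary mental-health services, ages 12-25).  Counts are
# the printed numerators; "missing" is the per-variable missing-data count,
# so each prevalence denominator is n_total - missing.  These are inputs to
# the descriptive re-computations, not outputs of this package.
cohort:
  n_total: 1107
use_prevalence:
  tobacco: {count: 351, missing: 52}
  alcohol: {count: 665, missing: 48}
  illicit: {count: 324, missing: 45}
  other: {count: 140, missing: 50}
  cocaine: {count: 35, missing: 57}
  cannabis: {count: 282, missing: 50}
  ats: {count: 84, missing: 0}
harm_prevalence:
  urge: {count: 559, missing: 40}
  led_to_problems: {count: 242, missing: 40}
  failed_expectations: {count: 205, missing: 40}
  caused_concerns: {count: 240, missing: 40}
polysubstance_including_tobacco_alcohol:
  none: 320
  one_only: 298
  polydrug: 449
  missing: 40
substance_groups:
  ats: 84
  cannabis_no_ats: 223
  alcohol_tobacco_other: 435
  none: 325
  missing: 40
group_cross_use:
  cannabis_in_ats_group: {count: 59, of: 84}
daily_tobacco_smokers:
  cannabis_co_use: {count: 114, of: 166}
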