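# Age-adjusted vital-sign thresholds used by the three severity scores.
# Version: 1
#
# The scores call for "age-adjusted" heart-rate and respiratory-rate
# thresholds without fixing universal values; published paediatric
# reference ranges differ between sources (APLS, IMCI, SIRS) by 10-20
# beats/breaths per minute.  The defaults below place the tachycardia and
# tachypnoea cut-offs near the 97.5th centile of the outcome-negative
# vital-sign distributions typical of young ARI cohorts, so that a point
# flags a genuinely unusual value rather than the upper quartile of normal
# illness.  The table is editable; every reported result should name the
# table version used.  Values strictly above an upper threshold (or
# strictly below a lower threshold, where the score counts bradycardia)
# score one point.
#
# Temperature bands: the original mSIRS uses core temperature > 38.5 or
# < 36.0 degrees C; when only axillary temperature is available the band
# is shifted to > 38.0 or < 35.5 degrees C (axillary reads about half a
# degree lower than core).
version: 1
age_bands:
  neonate:          # < 1 month
    hr_upper: 180.0
    hr_lower: 100.0
    rr_upper: 60.0
  infant:           # 1 to < 12 months
    hr_upper: 160.0
    hr_lower: 90.0
    rr_upper: 60.0
  child:            # 12 to 24 months
    hr_upper: 160.0
    hr_lower: 80.0
    rr_upper: 55.0
temperature:
  core:
    temp_upper: 38.5
    temp_lower: 36.0
  axillary:
    temp_upper: 38.0
    temp_lower: 35.5
crt_cutoff_seconds: 2.0
directionality:
  lqsofa_bradycardia: false   # LqSOFA scores tachycardia only
  msirs_bradycardia: true     # mSIRS scores both directions
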