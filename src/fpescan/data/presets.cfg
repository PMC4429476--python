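# Model presets and calibration constants (key = value).
# sex_bias_ratio: observed male:female incidence ratio the preset models.
# fpe_share: fraction of the incidence-ratio excess attributed to the locus.
# affected_risk_share: predicted share of affected females with the fully
#   unprotected genotype (the calibrated "modest deviation from ideal").
# derivation: how q and the efficacy are fixed (see docs/methods.md).

[ideal_4to1]
sex_bias_ratio = 4.0
fpe_share = 1.0
derivation = ideal

[ideal_5.25to1]
sex_bias_ratio = 5.25
fpe_share = 1.0
derivation = ideal

[half_fpe_5.25to1]
sex_bias_ratio = 5.25
fpe_share = 0.5
derivation = attenuated

[calibrated_4to1]
sex_bias_ratio = 4.0
fpe_share = 1.0
affected_risk_share = 0.97
derivation = calibrated

[power_analysis]
# headline GWAS scenario: mixed-sex case/pseudocontrol cohort
n_cases = 2678
n_controls = 2678
male_to_female_ratio = 5.25
n_tests = 500000
family_alpha = 0.05

[discovery_cohort]
n_affected = 208
n_unaffected = 151
tier1_n_tests = 451
tier2_n_tests = 6955
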