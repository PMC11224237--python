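# Default parameters of the synthetic population generator.
#
# The generator emulates the structure of a national health-survey extract
# restricted to adults under 65 with triplicate-averaged BP: a Gaussian
# copula ties age, BMI, SBP and HR together, DBP follows SBP linearly with
# residual scatter (giving a strong SBP-PP correlation), and sex / race /
# smoking are independent categoricals.
age_min: 18.0
age_max: 64.99
bmi_log_mean: 3.3142   # ln(27.5)
bmi_log_sd: 0.20
bmi_min: 15.0
bmi_max: 60.0
sbp_mean: 121.0
sbp_sd: 15.5
dbp_intercept: 40.0
dbp_slope: 0.30
dbp_resid_sd: 7.0
min_pp: 5.0
hr_mean: 72.0
hr_sd: 10.5
hr_min: 40.0
hr_max: 130.0
# latent correlations (Gaussian copula), order: age, bmi, sbp, hr, dbp-residual
corr_age_bmi: 0.05
corr_age_sbp: 0.45
corr_age_hr: -0.10
corr_bmi_sbp: 0.25
corr_bmi_hr: 0.05
corr_sbp_hr: 0.10
sex_levels: [female, male]
sex_probs: [0.51, 0.49]
race_levels: [white, black, hispanic, asian, other]
race_probs: [0.40, 0.22, 0.25, 0.09, 0.04]
smoking_levels: [never, former, current]
smoking_probs: [0.58, 0.22, 0.20]
measurement_noise_mean: 0.0
measurement_noise_sd: 0.0
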