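# Default run configuration.  Every value with a published counterpart
# matches it: 5-point smoothing window, <5% contact-area change, <50% limb
# rule, 70/30 split, 10 hidden neurons, noise bias/SD -1.0/7.2 mmHg over
# 100 realizations, 20-40 s raise window.
physics:
  rho_blood_kg_m3: 1060.0
  g_m_s2: 9.81
  pa_per_mmhg: 133.322
algorithm:
  filter_lo_hz: 0.5
  filter_hi_hz: 10.0
  prominence_frac: 0.3
  smooth_window: 5
  normalize_after_smooth: false
  fit_tol: 1.0e-10
  fit_start_widths: [2.0, 5.0, 10.0]
  pp_grid_points: 4001
validity:
  contact_area_max_frac: 0.05
  limb_max_frac: 0.5
  linearity_min_r2: 0.9
  monotone_min_frac: 0.9
  percent_increase: 0.10
  raise_min_s: 20.0
  raise_max_s: 40.0
screening:
  train_frac: 0.7
  hidden_units: 10
  lbfgs_tol: 1.0e-6
  max_iter: 500
  noise_mean_mmhg: -1.0
  noise_sd_mmhg: 7.2
  n_realizations: 100
seed: 0
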