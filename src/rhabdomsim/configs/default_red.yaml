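depth:
  dz: 5.0
  length: 450.0
include_beta_band: true
pigments:
- alpha_M: 7.5
  alpha_R: 6.0
  lambda_max_M: 495.0
  lambda_max_R: 515.0
- alpha_M: 7.5
  alpha_R: 6.0
  lambda_max_M: 495.0
  lambda_max_R: 515.0
- alpha_M: 7.5
  alpha_R: 6.0
  lambda_max_M: 505.0
  lambda_max_R: 545.0
- alpha_M: 7.5
  alpha_R: 6.0
  lambda_max_M: 505.0
  lambda_max_R: 545.0
- alpha_M: 7.5
  alpha_R: 6.0
  lambda_max_M: 505.0
  lambda_max_R: 545.0
- alpha_M: 7.5
  alpha_R: 6.0
  lambda_max_M: 505.0
  lambda_max_R: 545.0
- alpha_M: 7.5
  alpha_R: 6.0
  lambda_max_M: 505.0
  lambda_max_R: 545.0
- alpha_M: 7.5
  alpha_R: 6.0
  lambda_max_M: 505.0
  lambda_max_R: 545.0
- alpha_M: 7.5
  alpha_R: 6.0
  lambda_max_M: 505.0
  lambda_max_R: 545.0
screening:
  alpha_S: 20.0
  lambda_half: 600.0
  steepness: 0.05
  z_range:
  - 230.0
  - 420.0
tapetum_reflectance: 1.0
wavelength_grid:
  start: 300.0
  step: 1.0
  stop: 700.0
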