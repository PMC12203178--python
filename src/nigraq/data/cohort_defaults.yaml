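# Paper-derived default cohort design (version 1).
#
# Group sizes, ages, sex proportions and per-ROI QSM baseline means/SDs follow
# the published visit-1 cohort table of the longitudinal nigral-iron study the
# generator emulates; annual slopes follow its reported mixed-model estimates
# (only the PD posteroventral slopes are nonzero).  R2* entries are marked
# "derived": the source prints group contrasts and slopes but no R2* group
# table, so means/SDs are back-computed from the printed percent differences
# and standard errors.  Values not printed anywhere (lateral correlation,
# variance split, covariate links) are realistic choices documented in
# docs/methods.md.
version: 1
visit_intervals:  # years, mean and SD of each between-visit gap
  - {mean: 2.1, sd: 0.2}
  - {mean: 2.2, sd: 0.4}
age_range: [18.0, 80.0]
groups:
  HV:   {n_per_visit: [44, 36, 28],  age_mean: 62.3, age_sd: 9.7, male_prop: 0.545}
  iRBD: {n_per_visit: [49, 20, 11],  age_mean: 67.7, age_sd: 5.0, male_prop: 0.878}
  PD:   {n_per_visit: [127, 88, 50], age_mean: 62.3, age_sd: 9.0, male_prop: 0.598}
# fraction of the cross-sectional SD attributed to the between-subject
# (random-intercept) component; residual SD = sqrt(1 - f^2) * SD
between_subject_fraction: 0.8
# cross-sectional correlation between QSM and R2* for the same ROI
modality_corr: 0.88
lateral:
  offset: 0.0        # systematic left-minus-right difference, measurement units
  correlation: 0.85  # cross-sectional left-right correlation
covariate_effects:
  beta_age: 0.0                # per year of baseline age, both modalities
  beta_sex_male: {qsm_ppm: 0.0, r2s_hz: 1.4}
qsm_ppm:
  mean:
    whole_SN:       {HV: 0.118, iRBD: 0.130, PD: 0.128}
    ventral:        {HV: 0.122, iRBD: 0.134, PD: 0.136}
    posteroventral: {HV: 0.103, iRBD: 0.110, PD: 0.120}
    anteroventral:  {HV: 0.140, iRBD: 0.155, PD: 0.150}
    dorsal:         {HV: 0.112, iRBD: 0.125, PD: 0.118}
    posterodorsal:  {HV: 0.097, iRBD: 0.105, PD: 0.106}
    anterodorsal:   {HV: 0.121, iRBD: 0.137, PD: 0.125}
    STN:            {HV: 0.089, iRBD: 0.091, PD: 0.093}
  sd:
    whole_SN:       {HV: 0.031, iRBD: 0.041, PD: 0.034}
    ventral:        {HV: 0.032, iRBD: 0.044, PD: 0.038}
    posteroventral: {HV: 0.027, iRBD: 0.038, PD: 0.033}
    anteroventral:  {HV: 0.037, iRBD: 0.050, PD: 0.044}
    dorsal:         {HV: 0.032, iRBD: 0.039, PD: 0.030}
    posterodorsal:  {HV: 0.027, iRBD: 0.037, PD: 0.025}
    anterodorsal:   {HV: 0.036, iRBD: 0.041, PD: 0.035}
    STN:            {HV: 0.025, iRBD: 0.027, PD: 0.022}
  slope_per_year:
    posteroventral: {HV: 0.0, iRBD: 0.0, PD: 0.0026}
r2s_hz:  # derived (see header note)
  mean:
    posteroventral: {HV: 25.4, iRBD: 26.2, PD: 27.2}
  sd:
    posteroventral: {HV: 3.4, iRBD: 3.4, PD: 3.4}
  slope_per_year:
    posteroventral: {HV: 0.0, iRBD: 0.0, PD: 0.292}
# optional tabular covariates (per subject); link_roi deviates drive the
# correlation with the posteroventral QSM subject intercept
covariates:
  disease_duration_years:
    groups: {iRBD: {mean: 2.4, sd: 3.6}, PD: {mean: 1.4, sd: 1.0}}
    corr_with_posteroventral_qsm: 0.31
    min: 0.0
  nm_cvol:
    groups:
      HV: {mean: 0.26, sd: 0.05}
      iRBD: {mean: 0.24, sd: 0.05}
      PD: {mean: 0.21, sd: 0.05}
    corr_with_posteroventral_qsm: -0.25
    min: 0.0
  dat_sbr_putamen:
    groups:
      HV: {mean: 2.8, sd: 0.5}
      iRBD: {mean: 2.2, sd: 0.5}
      PD: {mean: 1.5, sd: 0.4}
    corr_with_posteroventral_qsm: -0.25
    min: 0.0
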