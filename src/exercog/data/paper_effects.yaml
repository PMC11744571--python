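# Packaged effect profile: condition x time effects of the acute exercise-break
# crossover study (n = 71; SIT = uninterrupted sitting reference, MIC/VIC =
# moderate-/vigorous-intensity cycling; pre/post intervention).
#
# behavioral.dids are post-minus-pre change relative to SIT in z-score units.
# The generator injects the RT and ER effects on the raw scale (ms /
# proportion) after solving the normalisation-pool moments; because the
# inverse efficiency score is a deterministic function of RT and ER, the IES
# entry of the calibration condition pins down the between-subject RT spread
# and the IES entries of other conditions are emergent (see docs/methods.md).
#
# retinal.interaction_um are the condition x time interaction coefficients of
# the two-condition (sitting vs exercise) reduced design, in µm; retinal.dids
# are the three-condition marginal-means difference-in-differences.  The same
# split applies to causal_density (resting-state and whole-task blocks).
name: paper_effects
n_subjects: 71
covariates:
  female_prop: 0.507
  age_mean: 20.94
  age_sd: 1.93
  bmi_mean: 21.67
  bmi_sd: 3.8
behavioral:
  dids:
    MIC: {rt: -0.13, er: -0.36, ies: -0.20}
    VIC: {rt: -0.22, er: -0.53, ies: -0.33}
  calibration_condition: MIC
  rt_median_ms: 680.0
  rt_sigma_log: 0.20
  block_rt_scale: {baseline: 1.0, color_dual: 1.15, lexical_dual: 1.25}
  er_mean: 0.10
  er_sd: 0.08
  rt_sex_effect_log: 0.04
  rt_age_effect_log_per_yr: 0.008
  omission_fraction: 0.2
retinal:
  interaction_um: {crae: 4.46, crve: 6.34}
  dids:
    MIC: {crae: 0.27, crve: 1.14}
    VIC: {crae: 3.03, crve: 3.72}
  crae_mean_um: 150.0
  crve_mean_um: 200.0
  between_subject_sd_um: 15.0
  residual_sd_um: 3.0
causal_density:
  resting:
    interaction: 0.37
    dids: {MIC: 0.17, VIC: 0.17}
    base: 0.30
    between_subject_sd: 0.08
    residual_sd: 0.10
  task:
    interaction: 0.06
    dids: {MIC: 0.004, VIC: 0.007}
    base: 0.25
    between_subject_sd: 0.05
    residual_sd: 0.02
mediation:
  a: 1.0
  b: -0.82
  c_prime: -0.51
  noise_sd: 0.1
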