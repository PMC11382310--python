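# Full pipeline on a synthetic cohort at the default calibration.
# Run:  ril-mediation run --config examples/config.yaml --out out/
simulate:
  n: 734
  seed: 1
seed: 1
screen_alpha: 0.05
forced: [age, surgery]
criterion: wald_p        # or: aic
distance_scale: logit    # or: probability
mediation:
  interaction: false
  ci_method: delta       # or: bootstrap
subgroup_by: surgery
output_dir: ril_mediation_out
log_level: INFO
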