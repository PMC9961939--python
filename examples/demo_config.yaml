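# Demo run configuration: a small synthetic cohort, full pipeline.
#   corticorl --config examples/demo_config.yaml --out corticorl_demo
seed: 3
simulate:
  n_admissions: 300
train:
  epochs: 250
explain:
  n_estimators: 200
  max_lrp_states: 200
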