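# Non-dialysis: SF-36 Vitality change from baseline (vs placebo)
run:
  input_path: src/hifnma/data/nd_sf36.csv
  outcome_id: sf36_vitality
  analysis_set_id: all
  reference: placebo
  seed: 1
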