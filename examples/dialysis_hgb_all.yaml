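# Dialysis, all trials: Hgb change from baseline (g/dL) vs ESA
run:
  input_path: src/hifnma/data/dialysis_hgb.csv
  outcome_id: hgb_cfb
  analysis_set_id: all
  reference: ESA
  seed: 1
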