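# Non-dialysis, all patients: MACE hazard ratios (roxadustat, vadadustat vs ESA)
run:
  input_path: src/hifnma/data/nd_mace.csv
  outcome_id: mace
  analysis_set_id: all
  reference: ESA
  seed: 1
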