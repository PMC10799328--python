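# Non-dialysis, ESA non-users at baseline: MACE (daprodustat, roxadustat vs ESA)
run:
  input_path: src/hifnma/data/nd_mace.csv
  outcome_id: mace
  analysis_set_id: esa_nonuser
  reference: ESA
  seed: 1
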