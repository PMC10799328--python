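# Synthetic design mimicking the non-dialysis MACE evidence base:
# three HIF-PHI nodes vs an ESA reference in a star, per-edge SEs matching
# the precision of the published intervals, true log HRs at the published
# point estimates.
schema_version: 1
design:
  nodes: [ESA, daprodustat, roxadustat, vadadustat]
  reference: ESA
  outcome_id: mace
  true_basic_parameters:
    daprodustat: -0.051
    roxadustat: -0.117
    vadadustat: 0.157
  trials_per_edge:
    - edge: [daprodustat, ESA]
      count: 1
    - edge: [roxadustat, ESA]
      count: 1
    - edge: [vadadustat, ESA]
      count: 2
  se_model: fixed
  fixed_se:
    - edge: [daprodustat, ESA]
      se: 0.105
    - edge: [roxadustat, ESA]
      se: 0.203
    - edge: [vadadustat, ESA]
      se: 0.107
  seed: 20230
  n_replicates: 200
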