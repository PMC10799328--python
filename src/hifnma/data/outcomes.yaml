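schema_version: 1
outcomes:
  hgb_cfb:
    analysis_scale: identity
    reporting_scale: identity
    units: g/dL
  mace:
    analysis_scale: log
    reporting_scale: exponentiated
    units: HR
  sf36_vitality:
    analysis_scale: identity
    reporting_scale: identity
    units: points
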