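schema_version: 1
analysis_sets:
  all:
    description: all patients / all trials
    include_tags: [all]
    node_merge_map: &esa_merge
      darbepoetin: ESA
      epoetin: ESA
      rHEpo: ESA
  esa_nonuser:
    description: non-dialysis patients who were ESA non-users at baseline
    include_tags: [esa_nonuser]
    node_merge_map: *esa_merge
  prevalent:
    description: trials in predominantly prevalent dialysis patients
    include_tags: [prevalent]
    node_merge_map: *esa_merge
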