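trial_id,treatment,comparator,outcome_id,estimate,ci_lower,ci_upper,se,population_tags,n
DAP-POOLED,daprodustat,ESA,hgb_cfb,0.16,0.08,0.24,,all,
ROX-POOLED,roxadustat,ESA,hgb_cfb,0.20,0.14,0.27,,all,
VADA-POOLED,vadadustat,ESA,hgb_cfb,-0.17,-0.26,-0.09,,all,
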