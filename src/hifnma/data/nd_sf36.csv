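trial_id,treatment,comparator,outcome_id,estimate,ci_lower,ci_upper,se,population_tags,n
ASCEND-NHQ,daprodustat,placebo,sf36_vitality,5.38,0.78,9.93,,all,
ROX-POOLED,roxadustat,placebo,sf36_vitality,0.67,0.02,1.32,,all,
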