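trial_id,treatment,comparator,outcome_id,estimate,ci_lower,ci_upper,se,population_tags,n
DOLOMITES,roxadustat,darbepoetin,mace,0.89,0.60,1.33,,all;esa_nonuser,
PRO2TECT-POOLED,vadadustat,darbepoetin,mace,1.17,1.01,1.36,,all,
ASCEND-ND,daprodustat,darbepoetin,mace,0.95,0.77,1.16,,esa_nonuser,
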