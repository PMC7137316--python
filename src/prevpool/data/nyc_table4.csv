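label,p_hat,ci_lower,ci_upper,n
# published NYC aggregates: gold-standard survey column (2013-14 NYC HANES, in-care adults, n=1135)
# and post-stratified EHR column (2013 NYC Macroscope, n=716076); decimals of the printed percentages
hypertension/survey,0.343,0.313,0.374,1135
hypertension/ehr,0.347,0.346,0.348,716076
diabetes/survey,0.133,0.113,0.156,1135
diabetes/ehr,0.149,0.149,0.150,716076
smoking/survey,0.173,0.151,0.199,1135
smoking/ehr,0.150,0.149,0.151,716076
obesity/survey,0.317,0.287,0.348,1135
obesity/ehr,0.280,0.279,0.281,716076
depression/survey,0.190,0.166,0.216,1135
depression/ehr,0.083,0.083,0.084,716076
influenza/survey,0.486,0.454,0.518,1135
influenza/ehr,0.217,0.216,0.218,716076
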