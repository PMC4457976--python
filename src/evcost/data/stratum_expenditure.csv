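stratum,n_facilities,avg_employees,avg_population_served,exp_human_resources,exp_materials,exp_public_funds,exp_total
urban,7,134.00,117687.00,8337175.71,1038666.67,3380284.76,12756127.14
suburban,10,116.00,47260.00,9099476.35,1532670.48,2941083.97,13573230.79
all,17,123.00,76259.00,17436651.90,2571336.98,6321368.73,26329357.62
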