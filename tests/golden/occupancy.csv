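# schema_version=1
k,observed_pct,null_mean_pct,null_sd_pct,z_score,n_synapses,n_sims,radius_nm,n_synapses_off_shaft,seed
1,52.0,38.0,9.293403409880339,1.506444881658297,25,50,500.0,0,12
2,0.0,7.36,5.90316414635198,-1.24678897918641,25,50,500.0,0,12
3,0.0,1.04,1.7723499907738083,-0.5867915509994366,25,50,500.0,0,12
4,0.0,0.0,0.0,,25,50,500.0,0,12
5,0.0,0.0,0.0,,25,50,500.0,0,12
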