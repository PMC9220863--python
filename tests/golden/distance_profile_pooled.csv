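# schema_version=1
dendrite_id,species,bin_label,bin_lo_um,bin_hi_um,count,fraction,reachable
pooled,rna1,0-25,0.0,25.0,114,0.95,True
pooled,rna1,25-50,25.0,50.0,6,0.05,True
pooled,rna1,50-75,50.0,75.0,0,0.0,False
pooled,rna1,75-100,75.0,100.0,0,0.0,False
pooled,rna1,100-125,100.0,125.0,0,0.0,False
pooled,rna1,125-150,125.0,150.0,0,0.0,False
pooled,rna1,>150,150.0,inf,0,0.0,False
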