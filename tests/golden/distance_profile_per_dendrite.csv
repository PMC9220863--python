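# schema_version=1
dendrite_id,species,bin_label,bin_lo_um,bin_hi_um,count,fraction,reachable
1,rna1,0-25,0.0,25.0,22,1.0,True
1,rna1,25-50,25.0,50.0,0,0.0,True
1,rna1,50-75,50.0,75.0,0,0.0,False
1,rna1,75-100,75.0,100.0,0,0.0,False
1,rna1,100-125,100.0,125.0,0,0.0,False
1,rna1,125-150,125.0,150.0,0,0.0,False
1,rna1,>150,150.0,inf,0,0.0,False
2,rna1,0-25,0.0,25.0,24,0.96,True
2,rna1,25-50,25.0,50.0,1,0.04,True
2,rna1,50-75,50.0,75.0,0,0.0,False
2,rna1,75-100,75.0,100.0,0,0.0,False
2,rna1,100-125,100.0,125.0,0,0.0,False
2,rna1,125-150,125.0,150.0,0,0.0,False
2,rna1,>150,150.0,inf,0,0.0,False
3,rna1,0-25,0.0,25.0,27,0.9,True
3,rna1,25-50,25.0,50.0,3,0.1,True
3,rna1,50-75,50.0,75.0,0,0.0,False
3,rna1,75-100,75.0,100.0,0,0.0,False
3,rna1,100-125,100.0,125.0,0,0.0,False
3,rna1,125-150,125.0,150.0,0,0.0,False
3,rna1,>150,150.0,inf,0,0.0,False
4,rna1,0-25,0.0,25.0,18,0.9473684210526315,True
4,rna1,25-50,25.0,50.0,1,0.05263157894736842,True
4,rna1,50-75,50.0,75.0,0,0.0,False
4,rna1,75-100,75.0,100.0,0,0.0,False
4,rna1,100-125,100.0,125.0,0,0.0,False
4,rna1,125-150,125.0,150.0,0,0.0,False
4,rna1,>150,150.0,inf,0,0.0,False
5,rna1,0-25,0.0,25.0,23,0.9583333333333334,True
5,rna1,25-50,25.0,50.0,1,0.041666666666666664,True
5,rna1,50-75,50.0,75.0,0,0.0,False
5,rna1,75-100,75.0,100.0,0,0.0,False
5,rna1,100-125,100.0,125.0,0,0.0,False
5,rna1,125-150,125.0,150.0,0,0.0,False
5,rna1,>150,150.0,inf,0,0.0,False
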