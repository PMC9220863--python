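# schema_version=1
bin_lo_nm,bin_hi_nm,observed_fraction,null_fraction,observed_cumulative,null_cumulative
0.0,500.0,0.49166666666666664,0.491,0.49166666666666664,0.491
500.0,1000.0,0.225,0.337,0.7166666666666667,0.8280000000000001
1000.0,1500.0,0.15833333333333333,0.10633333333333334,0.875,0.9343333333333335
1500.0,2000.0,0.06666666666666667,0.03866666666666667,0.9416666666666667,0.9730000000000001
2000.0,2500.0,0.058333333333333334,0.014333333333333333,1.0,0.9873333333333334
2500.0,3000.0,0.0,0.007,1.0,0.9943333333333334
3000.0,3500.0,0.0,0.002,1.0,0.9963333333333334
3500.0,4000.0,0.0,0.0013333333333333333,1.0,0.9976666666666667
4000.0,4500.0,0.0,0.0003333333333333333,1.0,0.998
4500.0,inf,0.0,0.002,1.0,1.0
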