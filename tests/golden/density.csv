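# schema_version=1
species,compartment,dendrite_id,n_spots,area_px,density_px,density_per_nm2
rna1,soma,,280,5013,0.055854777578296426,4.833296058695202e-06
rna1,nucleus,,75,1245,0.060240963855421686,5.212847061583272e-06
rna1,dendrite,1.0,22,1572,0.013994910941475827,1.2110252842813047e-06
rna1,dendrite,2.0,25,1667,0.014997000599880024,1.2977393704601428e-06
rna1,dendrite,3.0,30,1675,0.01791044776119403,1.5498494547274446e-06
rna1,dendrite,4.0,19,1645,0.011550151975683891,9.994723180689143e-07
rna1,dendrite,5.0,24,1683,0.0142602495543672,1.233985899782992e-06
rna1,dendrites_pooled,,120,8242,0.01455957291919437,1.259887326701514e-06
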