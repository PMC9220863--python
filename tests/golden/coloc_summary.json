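{
  "ks_p": 0.256817493920408,
  "ks_statistic": 0.11252923734276299,
  "mode": "self",
  "n_null_distances": 3000,
  "n_observed_distances": 120,
  "n_sims": 25,
  "schema_version": "1",
  "seed": 11,
  "species": "rna1"
}
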