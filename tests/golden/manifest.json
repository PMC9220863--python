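{
  "assignment.csv": "72272ccb5b1a75f499f71386c395941efb3103c9564a94e1c5c25360de87e480",
  "coloc_bins.csv": "c0c2fa37025683889487c85d991b8207c9b3b7369d458dbba753632b4b7960a0",
  "coloc_summary.json": "044a741f5684cd91169203503cd33002f26afc78746cf83b9e3fdbce08e72159",
  "density.csv": "e739336b22193ab9e00fe321b46ce3b833e30e91604cfbb264e9048667c7cf65",
  "distance_profile_per_dendrite.csv": "fb35c755f5ebf256f300956759593c980252e7c5c76c4981c8ea341c7a93d95b",
  "distance_profile_pooled.csv": "23082213c1c434588422e7f50476cc51a819fd9ce9e40855ba357f732e216e1a",
  "occupancy.csv": "0b37e51acc17b7f7ce436cb3b7362c67052a01b84d19cbf645f39664d42292ef",
  "resolved_config.json": "3a47a44b493631a5384dcb44323078b6dc4607a24be9852ec971a38b93853322",
  "skeleton_distances.csv": "d379c103fd992b2853899d22982dd2bacb7d8cb5d4eadd2a50f1cbec6cd206f5"
}
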