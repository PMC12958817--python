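{
  "qtl_marker": "snp_2_24600000",
  "qtl_index": 152,
  "qtl_beta": [
    -0.9553205549119953,
    -0.7893522173763263
  ],
  "trait_names": [
    "CL_NIS",
    "CL_IS"
  ]
}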