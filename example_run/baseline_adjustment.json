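{
  "coefficient": 0.08677709945214972,
  "se": 0.08911438661219302,
  "p_value": 0.33016973088977486
}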