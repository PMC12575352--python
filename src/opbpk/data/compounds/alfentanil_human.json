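{
  "name": "alfentanil",
  "species": "human",
  "logP": 2.26,
  "pka_list": [[6.5, "base"]],
  "fup": 0.1579,
  "rbp": 1.0,
  "clsys_L_per_h": 53.931
}
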