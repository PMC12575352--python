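{
  "name": "sufentanil",
  "species": "human",
  "logP": 3.85,
  "pka_list": [[8.0, "base"]],
  "fup": 0.0891,
  "rbp": 1.0,
  "clsys_L_per_h": 58.55
}
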