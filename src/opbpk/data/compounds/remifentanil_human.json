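{
  "name": "remifentanil",
  "species": "human",
  "logP": 1.95,
  "pka_list": [[7.07, "base"]],
  "fup": 0.2657,
  "rbp": 1.0,
  "clsys_L_per_h": 58.553
}
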