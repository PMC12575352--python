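{
  "name": "fentanyl",
  "species": "rat",
  "logP": 4.05,
  "pka_list": [[8.77, "base"]],
  "fup": 0.083,
  "rbp": 1.01,
  "sw_mg_per_mL": 0.2,
  "clsys_L_per_h": 0.9,
  "_note": "fup/rbp from the published model parameterization; clsys allometric from the human value (62.66 x (0.25/70)^0.75)."
}
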