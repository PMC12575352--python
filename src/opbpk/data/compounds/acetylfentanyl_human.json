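{
  "name": "acetylfentanyl",
  "species": "human",
  "logP": 3.55,
  "pka_list": [[8.8, "base"]],
  "fup": 0.168,
  "rbp": 0.83,
  "sw_mg_per_mL": 0.59,
  "peff_1e4_cm_per_s": 3.81,
  "clsys_L_per_h": 62.66,
  "_note": "Physicochemistry from the published analog table; clsys is the shared measured fentanyl value used across the analog batch."
}
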