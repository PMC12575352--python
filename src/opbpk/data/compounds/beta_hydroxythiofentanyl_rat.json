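{
  "name": "beta-hydroxythiofentanyl",
  "species": "rat",
  "logP": 2.59,
  "pka_list": [[8.9, "base"]],
  "fup": 0.3225,
  "rbp": 1.04,
  "sw_mg_per_mL": 0.48,
  "peff_1e4_cm_per_s": 3.35,
  "clsys_L_per_h": 0.45,
  "_note": "Physicochemistry from the published rat study table; clsys is a representative fentanyl-class rat value (the measured in-vivo clearance is not tabulated in the open literature)."
}
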