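{
  "name": "Tc99m-tetrofosmin",
  "kp": {
    "lung": 1.56,
    "heart": 8.17,
    "kidney": 29.1,
    "liver": 1.88,
    "thyroid": 13.4,
    "other": 19.0,
    "muscle": 1.19,
    "adipose": 1.04,
    "gi": 0.26,
    "spleen": 1.18,
    "pancreas": 1.28
  },
  "ps_heart": 0.016,
  "ps_kidney": 0.247,
  "cl_renal": 0.156,
  "cl_liver": 0.0683,
  "k_gb": 0.005,
  "blood_plasma_ratio": 0.8,
  "logp": 1.14,
  "pka": 8.3,
  "fu": 0.7353,
  "molecular_weight": 898.86,
  "compound_type": "monoprotic base"
}
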