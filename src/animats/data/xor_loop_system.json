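{
 "n_sensors": 0,
 "n_hidden": 3,
 "n_motors": 0,
 "tpm": [
  2,
  4,
  7,
  1,
  0,
  4,
  4,
  0
 ],
 "cm": [
  [
   0,
   1,
   1
  ],
  [
   1,
   0,
   1
  ],
  [
   1,
   1,
   0
  ]
 ],
 "state": 5,
 "expected": {
  "phi_effect_AB_over_ABC": 0.25,
  "phi_cause_AB_max": 0.33,
  "phi_effect_AB_max": 0.5,
  "phi_max_AB": 0.33,
  "n_concepts": 4,
  "big_phi": 0.92,
  "n_mc_elements": 3,
  "n_mc_concepts": 4
 }
}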