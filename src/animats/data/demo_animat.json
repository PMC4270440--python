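{
 "n_sensors": 2,
 "n_hidden": 4,
 "n_motors": 2,
 "tpm": [
  8,
  72,
  136,
  200,
  16,
  80,
  144,
  208,
  28,
  92,
  156,
  220,
  4,
  68,
  132,
  196,
  0,
  64,
  128,
  192,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  32,
  96,
  160,
  224,
  24,
  88,
  152,
  216,
  16,
  80,
  144,
  208,
  28,
  92,
  156,
  220,
  20,
  84,
  148,
  212,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  48,
  112,
  176,
  240,
  8,
  72,
  136,
  200,
  16,
  80,
  144,
  208,
  28,
  92,
  156,
  220,
  4,
  68,
  132,
  196,
  0,
  64,
  128,
  192,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  32,
  96,
  160,
  224,
  24,
  88,
  152,
  216,
  16,
  80,
  144,
  208,
  28,
  92,
  156,
  220,
  20,
  84,
  148,
  212,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  48,
  112,
  176,
  240,
  8,
  72,
  136,
  200,
  16,
  80,
  144,
  208,
  28,
  92,
  156,
  220,
  4,
  68,
  132,
  196,
  0,
  64,
  128,
  192,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  32,
  96,
  160,
  224,
  24,
  88,
  152,
  216,
  16,
  80,
  144,
  208,
  28,
  92,
  156,
  220,
  20,
  84,
  148,
  212,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  48,
  112,
  176,
  240,
  8,
  72,
  136,
  200,
  16,
  80,
  144,
  208,
  28,
  92,
  156,
  220,
  4,
  68,
  132,
  196,
  0,
  64,
  128,
  192,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  32,
  96,
  160,
  224,
  24,
  88,
  152,
  216,
  16,
  80,
  144,
  208,
  28,
  92,
  156,
  220,
  20,
  84,
  148,
  212,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  16,
  80,
  144,
  208,
  48,
  112,
  176,
  240
 ],
 "cm": [
  [
   0,
   0,
   0,
   0,
   0,
   0,
   1,
   0
  ],
  [
   0,
   0,
   0,
   0,
   0,
   0,
   0,
   1
  ],
  [
   0,
   0,
   0,
   1,
   1,
   1,
   0,
   0
  ],
  [
   0,
   0,
   1,
   0,
   1,
   1,
   0,
   0
  ],
  [
   0,
   0,
   1,
   1,
   0,
   1,
   0,
   0
  ],
  [
   0,
   0,
   0,
   0,
   1,
   0,
   0,
   0
  ],
  [
   0,
   0,
   0,
   0,
   0,
   0,
   0,
   0
  ],
  [
   0,
   0,
   0,
   0,
   0,
   0,
   0,
   0
  ]
 ],
 "state": 84,
 "expected": {
  "whole_brain_n_concepts": 6,
  "whole_brain_sum_phi": 1.0714,
  "mc_elements": 3,
  "mc_big_phi": 0.92,
  "mc_n_concepts": 4
 }
}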