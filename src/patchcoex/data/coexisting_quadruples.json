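[
 {
  "area": 0.25,
  "macro": 0.5,
  "island_seed": 3,
  "spec_seed": 7,
  "replicate": 111
 },
 {
  "area": 0.25,
  "macro": 0.5,
  "island_seed": 3,
  "spec_seed": 7,
  "replicate": 170
 },
 {
  "area": 0.25,
  "macro": 0.5,
  "island_seed": 3,
  "spec_seed": 7,
  "replicate": 223
 },
 {
  "area": 0.25,
  "macro": 0.5,
  "island_seed": 3,
  "spec_seed": 7,
  "replicate": 230
 },
 {
  "area": 0.25,
  "macro": 0.5,
  "island_seed": 3,
  "spec_seed": 7,
  "replicate": 313
 },
 {
  "area": 0.15,
  "macro": 0.5,
  "island_seed": 3,
  "spec_seed": 7,
  "replicate": 230
 },
 {
  "area": 0.25,
  "macro": 0.5,
  "island_seed": 3,
  "spec_seed": 8,
  "replicate": 183
 },
 {
  "area": 0.4,
  "macro": 0.45,
  "island_seed": 13,
  "spec_seed": 9,
  "replicate": 74
 },
 {
  "area": 0.4,
  "macro": 0.45,
  "island_seed": 13,
  "spec_seed": 9,
  "replicate": 125
 }
]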