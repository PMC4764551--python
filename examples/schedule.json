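[
 {
  "condition": "single_A@0.1",
  "onset_s": 16.0,
  "duration_s": 6.0
 },
 {
  "condition": "double@0.1",
  "onset_s": 38.0,
  "duration_s": 6.0
 },
 {
  "condition": "double@0.1",
  "onset_s": 60.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_A@0.1",
  "onset_s": 82.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_B@0.1",
  "onset_s": 104.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_B@0.1",
  "onset_s": 126.0,
  "duration_s": 6.0
 },
 {
  "condition": "double@0.1",
  "onset_s": 148.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_B@0.1",
  "onset_s": 170.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_A@0.1",
  "onset_s": 192.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_A@0.1",
  "onset_s": 214.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_B@1",
  "onset_s": 252.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_B@1",
  "onset_s": 274.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_A@1",
  "onset_s": 296.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_A@1",
  "onset_s": 318.0,
  "duration_s": 6.0
 },
 {
  "condition": "double@1",
  "onset_s": 340.0,
  "duration_s": 6.0
 },
 {
  "condition": "double@1",
  "onset_s": 362.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_A@1",
  "onset_s": 384.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_B@1",
  "onset_s": 406.0,
  "duration_s": 6.0
 },
 {
  "condition": "double@1",
  "onset_s": 428.0,
  "duration_s": 6.0
 },
 {
  "condition": "single_B@1",
  "onset_s": 450.0,
  "duration_s": 6.0
 }
]
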