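# pipeline configuration example
crf: {r_max: 1.0, c50: 0.25, exponent_n: 2.0, r0: 0.0}
law: {k_scale: 2.0, gamma: 0.5}
design:
  duration_s: 6.0
  n_blocks: 19
  amp_noise_sd: 0.15
  n_runs: 5
stitch: {n_restarts: 8}
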