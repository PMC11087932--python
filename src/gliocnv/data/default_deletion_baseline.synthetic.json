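{
  "slope": -1.9999999893333342,
  "intercept": 1.999906661333067,
  "residual_sd": 8.684962358643171e-05,
  "n_points": 9,
  "t_range": [
    0.1,
    0.9
  ],
  "provenance": "synthetic noiseless admixture series (hg38 grid, depth 10000, fractions 0.1..0.9)"
}
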