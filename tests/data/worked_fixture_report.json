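{
  "branching": {
    "ci95_kb": [
      0.5231733182144044,
      0.5775856402932059
    ],
    "kb [1/day]": 0.5503794792538051,
    "kb_pinned [1/day]": 0.4779857448522573,
    "log_intercept": -0.45849365120980223,
    "n": 9
  },
  "feedback": {
    "ci95_kd0": null,
    "ci95_w0": null,
    "kd0 [1/day]": 1.5323370279576174,
    "n": 2994,
    "r2": 0.8934029759054756,
    "slope [1/(day*um)]": -0.025334293109819307,
    "stderr_intercept": 0.005239550871332352,
    "stderr_slope": 0.0001599841061422934,
    "w0 [um]": 60.48469642769309
  },
  "seed": null,
  "tip_speed": {
    "n_tracks": 336,
    "sd [um/day]": 6.6673390409902975,
    "v0 [um/day]": 80.26104209003944
  }
}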