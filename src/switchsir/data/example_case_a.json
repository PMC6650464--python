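{
  "model": {
    "regimes": [
      {
        "Lambda": 0.3,
        "mu": 0.1,
        "beta": 0.8,
        "alpha": 0.2,
        "gamma": 0.3,
        "epsilon": 0.1,
        "sigma2": 0.4
      },
      {
        "Lambda": 0.5,
        "mu": 0.2,
        "beta": 0.6,
        "alpha": 0.1,
        "gamma": 0.2,
        "epsilon": 0.2,
        "sigma2": 0.2
      }
    ],
    "generator": [
      [
        -0.2,
        0.2
      ],
      [
        0.8,
        -0.8
      ]
    ],
    "h": 0.002,
    "l": null
  },
  "initial": {
    "S0": 0.3,
    "I0": 0.2,
    "r0": 1
  },
  "numerics": {
    "T": 1000.0,
    "dt": 0.01,
    "n_paths": 200,
    "seed": 0,
    "extinction_floor": 0.0001,
    "hist_bins": 40,
    "hist_s_range": [
      0.0,
      3.5
    ],
    "hist_i_range": [
      0.0,
      3.5
    ],
    "window": null
  },
  "outputs": {
    "trajectory_csv": null,
    "summary_json": null
  },
  "label": "two-regime reference, case a",
  "notes": []
}
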