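{
  "units": {
    "cl0_pop": "L/day",
    "v1": "L",
    "v2": "L",
    "q": "L/day",
    "imax": "fraction",
    "t50": "day",
    "gamma": "-",
    "omega_sq": "log-variance",
    "sigma_prop": "fraction",
    "sigma_add": "mg/L",
    "lbw_ref": "kg"
  },
  "values": {
    "cl0_pop": 0.279,
    "v1": 3.48,
    "v2": 4.06,
    "q": 0.795,
    "imax": 0.42,
    "t50": 40.0,
    "gamma": 1.5,
    "omega_sq": {
      "cl": 0.112,
      "v1": 0.047,
      "imax": 0.25
    },
    "sigma_prop": 0.2,
    "sigma_add": 0.2,
    "theta_size": 0.75,
    "theta_size_vol": 1.0,
    "lbw_ref": 52.5
  }
}
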