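{
  "fig1a": {"slope": -0.73, "intercept": 2.23, "r2": 0.89,
            "tol_slope": 0.05, "tol_intercept": 0.15, "tol_r2": 0.04},
  "fig1b": {"slope": -0.87, "intercept": 3.49, "r2": 0.87,
            "tol_slope": 0.05, "tol_intercept": 0.25, "tol_r2": 0.04},
  "fig3":  {"slope": 0.91, "intercept": -1.56, "r2": 0.90,
            "tol_slope": 0.05, "tol_intercept": 0.25, "tol_r2": 0.04},
  "unicellular": {"r2": 0.66, "tol_r2": 0.06},
  "pic": {"slope": -0.60, "r2": 0.83, "tol_slope": 0.10, "tol_r2": 0.08}
}
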