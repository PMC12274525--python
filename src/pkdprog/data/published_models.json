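{
  "_comment": "Published linear eGFR-slope models for the ADPKD screening cohort (n=212). Protein predictors are standardized (z-scored) abundances; age in years; eGFR in mL/min/1.73m2; sex coded male=1; Mayo imaging class coded as dummies for 1C and pooled 1D-1E against the pooled 1A-1B reference. Response: annual eGFR slope in mL/min/1.73m2/year.",
  "proteome": {
    "n": 212,
    "r2": 0.334,
    "r2_adjusted": 0.314,
    "terms": {
      "(Intercept)": {"beta": -2.74, "ci": [-3.01, -2.47], "p": "<0.001"},
      "SERPINF1": {"beta": -0.63, "ci": [-0.96, -0.30], "p": "<0.001"},
      "GPX3": {"beta": 0.71, "ci": [0.42, 1.00], "p": "<0.001"},
      "AFM": {"beta": 0.40, "ci": [0.12, 0.67], "p": "0.005"},
      "FERMT3": {"beta": -0.49, "ci": [-0.76, -0.22], "p": "<0.001"},
      "CFHR1": {"beta": -0.34, "ci": [-0.61, -0.06], "p": "0.016"},
      "RARRES2": {"beta": -0.33, "ci": [-0.63, -0.03], "p": "0.030"}
    }
  },
  "clinical": {
    "n": 212,
    "r2": 0.251,
    "r2_adjusted": 0.233,
    "terms": {
      "(Intercept)": {"beta": -6.96, "ci": [-10.00, -3.92], "p": "<0.001"},
      "Age": {"beta": 0.04, "ci": [0.00, 0.08], "p": "0.049"},
      "Sex[Male]": {"beta": -0.52, "ci": [-1.11, 0.08], "p": "0.089"},
      "eGFR": {"beta": 0.04, "ci": [0.03, 0.06], "p": "<0.001"},
      "MAYO[1C]": {"beta": -0.48, "ci": [-1.22, 0.26], "p": "0.205"},
      "MAYO[1D-1E]": {"beta": -0.94, "ci": [-1.76, -0.12], "p": "0.026"}
    }
  },
  "combined": {
    "n": 212,
    "r2": 0.375,
    "r2_adjusted": 0.340,
    "terms": {
      "(Intercept)": {"beta": -3.58, "ci": [-6.73, -0.42], "p": "0.027"},
      "SERPINF1": {"beta": -0.37, "ci": [-0.74, 0.01], "p": "0.055"},
      "GPX3": {"beta": 0.58, "ci": [0.26, 0.90], "p": "<0.001"},
      "AFM": {"beta": 0.27, "ci": [-0.02, 0.57], "p": "0.069"},
      "FERMT3": {"beta": -0.48, "ci": [-0.75, -0.21], "p": "0.001"},
      "CFHR1": {"beta": -0.29, "ci": [-0.57, -0.02], "p": "0.036"},
      "RARRES2": {"beta": -0.33, "ci": [-0.62, -0.03], "p": "0.029"},
      "Age": {"beta": 0.01, "ci": [-0.03, 0.05], "p": "0.651"},
      "Sex[Male]": {"beta": -0.47, "ci": [-1.05, 0.11], "p": "0.110"},
      "eGFR": {"beta": 0.01, "ci": [-0.01, 0.03], "p": "0.186"},
      "MAYO[1C]": {"beta": -0.20, "ci": [-0.90, 0.50], "p": "0.577"},
      "MAYO[1D-1E]": {"beta": -0.77, "ci": [-1.53, 0.00], "p": "0.050"}
    }
  }
}
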