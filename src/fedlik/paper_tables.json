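{
  "schema": "fedlik.reference_tables/1",
  "description": "Printed regional, global, meta-analysis and federated-likelihood results of the CKD/hypertension case study, carried verbatim for exact reproduction of the pooling and RPAB arithmetic.",
  "parameters": ["intercept", "hypertension", "sex", "age"],
  "regions": ["British Columbia", "Alberta", "Manitoba", "Ontario", "Maritimes"],
  "site_n": {
    "British Columbia": 1700,
    "Alberta": 8002,
    "Manitoba": 6089,
    "Ontario": 23946,
    "Maritimes": 2604,
    "Global": 42341
  },
  "regional_models": {
    "Global": {
      "estimates": [-7.0460, 0.2542, -0.0737, 0.0770],
      "se": [0.1007, 0.0300, 0.0291, 0.0014],
      "ci_lower": [-7.24, 0.20, -0.13, 0.07],
      "ci_upper": [-6.85, 0.31, -0.02, 0.08]
    },
    "British Columbia": {
      "estimates": [-7.0588, 0.5660, -0.1012, 0.0740],
      "se": [0.5060, 0.1661, 0.1462, 0.0070],
      "ci_lower": [-8.08, 0.25, -0.39, 0.06],
      "ci_upper": [-6.09, 0.90, 0.19, 0.09]
    },
    "Alberta": {
      "estimates": [-7.2386, 0.4661, -0.0442, 0.0753],
      "se": [0.2456, 0.0823, 0.0708, 0.0034],
      "ci_lower": [-7.73, 0.31, -0.18, 0.07],
      "ci_upper": [-6.76, 0.63, 0.09, 0.08]
    },
    "Manitoba": {
      "estimates": [-6.6667, 0.3651, -0.2778, 0.0714],
      "se": [0.2581, 0.0820, 0.0780, 0.0036],
      "ci_lower": [-7.18, 0.21, -0.43, 0.06],
      "ci_upper": [-6.17, 0.53, -0.12, 0.08]
    },
    "Ontario": {
      "estimates": [-7.0716, 0.1634, -0.0034, 0.0780],
      "se": [0.1338, 0.0387, 0.0384, 0.0019],
      "ci_lower": [-7.34, 0.09, -0.08, 0.07],
      "ci_upper": [-6.81, 0.24, 0.07, 0.08]
    },
    "Maritimes": {
      "estimates": [-7.1802, 0.4664, -0.2726, 0.0807],
      "se": [0.3915, 0.1302, 0.1084, 0.0054],
      "ci_lower": [-7.96, 0.21, -0.49, 0.07],
      "ci_upper": [-6.43, 0.73, -0.06, 0.09]
    }
  },
  "likelihood_models": {
    "max_loglik": {
      "regional": {
        "British Columbia": -618.57,
        "Alberta": -2702.45,
        "Manitoba": -2184.38,
        "Ontario": -8939.61,
        "Maritimes": -1083.57
      },
      "increment_0.01": {
        "British Columbia": -618.70,
        "Alberta": -2703.44,
        "Manitoba": -2184.42,
        "Ontario": -8940.51,
        "Maritimes": -1083.57,
        "Combined": -15567.06
      },
      "increment_0.005": {
        "British Columbia": -618.59,
        "Alberta": -2702.45,
        "Manitoba": -2184.41,
        "Ontario": -8940.50,
        "Maritimes": -1083.57,
        "Combined": -15564.56
      },
      "Global": -15563.98
    },
    "combined_estimates": {
      "increment_0.01": [-7.2856, 0.2476, -0.0754, 0.0805],
      "increment_0.005": [-6.9406, 0.2576, -0.0754, 0.0755]
    }
  },
  "summary": {
    "common_effect": {
      "estimates": [-7.0131, 0.2646, -0.0721, 0.0765],
      "ci_lower": [-7.2644, 0.2043, -0.1294, 0.0738],
      "ci_upper": [-6.8124, 0.3248, -0.0149, 0.0793],
      "note": "The printed common-effect intercept -7.0131 is not reproducible by inverse-variance pooling of the regional rows (which gives -7.0445) and is not centred in its own interval; carried verbatim, flagged as a likely transcription issue."
    },
    "likelihood_0.01": {
      "estimates": [-7.2856, 0.2476, -0.0754, 0.0805],
      "li_lower": [-7.3356, 0.1876, -0.1254, 0.0805],
      "li_upper": [-7.2356, 0.2976, -0.0154, 0.0805]
    },
    "likelihood_0.005": {
      "estimates": [-6.9406, 0.2576, -0.0754, 0.0755],
      "li_lower": [-6.9956, 0.2026, -0.1304, 0.0755],
      "li_upper": [-6.8906, 0.3126, -0.0204, 0.0755]
    },
    "global": {
      "estimates": [-7.0460, 0.2542, -0.0737, 0.0770],
      "ci_lower": [-7.2444, 0.1955, -0.1308, 0.0743],
      "ci_upper": [-6.8495, 0.3130, -0.0166, 0.0798]
    }
  },
  "heterogeneity_hypertension": {"i_squared_pct": 80, "p": 0.0005},
  "rpab_hypertension_pct": {
    "common_effect": 4.09,
    "likelihood_0.01": 2.60,
    "likelihood_0.005": 1.34
  }
}
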