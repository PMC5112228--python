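{
  "batch_constants": {
    "glucose": {"alpha": 0.6111, "beta": 0.0002},
    "nitrogen": {"alpha": 0.0112, "beta": -0.000003},
    "phosphorous": {"alpha": 0.1765, "beta": -0.000005},
    "rhamnolipid": {"alpha": 0.3091, "beta": -0.000009}
  },
  "fedbatch_constants": {
    "constant": {
      "glucose":     {"Umax": 0.0258, "l": 0.01, "h": 0.01, "F": 0.45, "Ki": 0.01, "Si": 0.29,   "Sgf": 0.41, "Snf": 0.1196, "Spf": 0.0755, "alpha": 0.824,   "beta": 1.0,    "gamma": 0.85,    "eta": 0.45,    "Ks": 0.387,  "Muf": 0.005,  "Y": 0.421, "Xf": 3.04, "Pf": 0.637, "Sf": 0.41},
      "nitrogen":    {"Umax": 0.1283, "l": 0.01, "h": 0.01, "F": 0.45, "Ki": 0.01, "Si": 0.071,  "Sgf": 1.56, "Snf": 0.0495, "Spf": 0.0567, "alpha": 0.633,   "beta": 0.699,  "gamma": -12.725, "eta": -7.577,  "Ks": 5.0972, "Muf": 0.0086, "Y": 0.421, "Xf": 3.12, "Pf": 0.626, "Sf": 0.0495},
      "phosphorous": {"Umax": 0.01161, "l": 0.01, "h": 0.01, "F": 0.45, "Ki": 0.01, "Si": 0.1104, "Sgf": 1.5,  "Snf": 0.2779, "Spf": 0.2987, "alpha": 0.966,   "beta": 2.59,   "gamma": 2.4,     "eta": 21.3,    "Ks": 1.28,   "Muf": 0.006,  "Y": 0.421, "Xf": 2.87, "Pf": 0.734, "Sf": 0.87}
    },
    "exponential": {
      "glucose":     {"Umax": 0.1366, "l": 0.01, "h": 0.01, "F": 0.45, "Ki": 0.01, "Si": 0.07,   "Sgf": 0.87, "Snf": 0.0109, "Spf": 0.1099, "alpha": 0.07512, "beta": 5.0972, "gamma": 0.6763,  "eta": 2.5618,  "Ks": 0.683,  "Muf": 0.005,  "Y": 0.421, "Xf": 3.14, "Pf": 0.734, "Sf": 0.87},
      "nitrogen":    {"Umax": 0.123,  "l": 0.01, "h": 0.01, "F": 0.45, "Ki": 0.01, "Si": 0.009,  "Sgf": 1.48, "Snf": 0.0393, "Spf": 0.0453, "alpha": 0.0078,  "beta": 0.4246, "gamma": 13.298,  "eta": 9.9924,  "Ks": 0.0106, "Muf": 0.011,  "Y": 0.421, "Xf": 3.32, "Pf": 0.666, "Sf": 0.393},
      "phosphorous": {"Umax": 0.12,   "l": 0.01, "h": 0.01, "F": 0.45, "Ki": 0.01, "Si": 0.0558, "Sgf": 1.42, "Snf": 0.3184, "Spf": 0.0326, "alpha": 0.891,   "beta": 0.282,  "gamma": -3.177,  "eta": -0.999,  "Ks": -0.00468, "Muf": 0.008, "Y": 0.421, "Xf": 3.02, "Pf": 0.634, "Sf": 0.0326}
    }
  },
  "model_parameters": {
    "constant": {
      "glucose":     {"mu_max": 0.13,   "alpha": 0.824,   "beta": 1.0,    "gamma": 0.85,    "eta": 0.45,
                      "Y_glucose": -0.00948, "Y_nitrogen": -0.06502, "Y_phosphorous": -0.05958, "Y_product": -0.00936},
      "nitrogen":    {"mu_max": 0.1283, "alpha": 0.633,   "beta": 0.699,  "gamma": -12.725, "eta": -7.577,
                      "Y_glucose": -0.005,   "Y_nitrogen": -0.00192, "Y_phosphorous": -0.00193, "Y_product": -0.30264},
      "phosphorous": {"mu_max": 0.1161, "alpha": 0.966,   "beta": 2.59,   "gamma": 22.4,    "eta": 1.3,
                      "Y_glucose": -0.00936, "Y_nitrogen": -0.0032,  "Y_phosphorous": -0.0037,  "Y_product": -0.25359}
    },
    "exponential": {
      "glucose":     {"mu_max": 0.1366, "alpha": 0.07512, "beta": 5.0972, "gamma": 0.6743,  "eta": 2.5481,
                      "Y_glucose": -0.48396, "Y_nitrogen": -0.06502, "Y_phosphorous": -0.05958, "Y_product": 0.114277},
      "nitrogen":    {"mu_max": 0.133,  "alpha": 0.0078,  "beta": 0.4241, "gamma": 3.298,   "eta": 9.9924,
                      "Y_glucose": -0.00507, "Y_nitrogen": -0.00192, "Y_phosphorous": -0.00193, "Y_product": -0.30264},
      "phosphorous": {"mu_max": 0.122,  "alpha": 0.891,   "beta": 0.282,  "gamma": -3.177,  "eta": -0.999,
                      "Y_glucose": -0.00488, "Y_nitrogen": -0.0032,  "Y_phosphorous": -0.0037,  "Y_product": -0.25359}
    }
  },
  "medium_g_l": {"glucose": 10.0, "nitrogen": 1.7, "phosphorous": 3.0}
}
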