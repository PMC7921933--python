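{
  "description": "Minimum / average / maximum levels of the measured mechanical properties of papaya skin and flesh used as material-model inputs. Units: E, sigma_y, Et in MPa; nu dimensionless; rho in kg/m^3.",
  "skin": {
    "E_MPa":       {"min": 2.0,  "avg": 6.0,  "max": 15.0},
    "sigma_y_MPa": {"min": 0.5,  "avg": 2.5,  "max": 4.0},
    "Et_MPa":      {"min": 0.02, "avg": 0.03, "max": 0.04},
    "nu":          {"min": 0.43, "avg": 0.44, "max": 0.45},
    "rho_kg_m3":   {"min": 1000.0, "avg": 1100.0, "max": 1200.0}
  },
  "flesh": {
    "E_MPa":       {"min": 0.5,   "avg": 2.0,   "max": 4.0},
    "sigma_y_MPa": {"min": 0.05,  "avg": 1.0,   "max": 1.8},
    "Et_MPa":      {"min": 0.002, "avg": 0.003, "max": 0.004},
    "nu":          {"min": 0.43,  "avg": 0.44,  "max": 0.45},
    "rho_kg_m3":   {"min": 1000.0, "avg": 1100.0, "max": 1200.0}
  }
}
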