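{
  "version": 1,
  "description": "Published clr statistics of 489 nutritionally balanced, high-yield (TN) specimens of 0.9-1.1-year-old Eucalyptus across southern-Brazil survey factors; the regional diagnostic standard.",
  "n": 489,
  "age_window": [0.9, 1.1],
  "parts": {
    "N":  {"mean": 2.9050,  "sd": 0.3048},
    "P":  {"mean": 0.0726,  "sd": 0.2618},
    "K":  {"mean": 2.1387,  "sd": 0.2878},
    "Mg": {"mean": 0.8880,  "sd": 0.2270},
    "Ca": {"mean": 2.0454,  "sd": 0.2962},
    "S":  {"mean": 0.3053,  "sd": 0.3024},
    "B":  {"mean": -4.8438, "sd": 0.4189},
    "Cu": {"mean": -4.0882, "sd": 0.3872},
    "Zn": {"mean": -2.7212, "sd": 0.4089},
    "Mn": {"mean": -3.2629, "sd": 0.3338},
    "Fe": {"mean": -0.2132, "sd": 0.4754},
    "Fv": {"mean": 6.7743,  "sd": 0.1453}
  }
}
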