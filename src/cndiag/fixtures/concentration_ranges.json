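{
  "version": 1,
  "description": "Observed min/median/max of tissue components over the 1861-tree survey, all in g/kg (micronutrients converted); used to keep synthetic draws within realistic bounds.",
  "parts": {
    "N":  {"min": 9.1,   "median": 21.9,  "max": 38.8},
    "P":  {"min": 0.5,   "median": 1.3,   "max": 3.3},
    "K":  {"min": 1.2,   "median": 9.4,   "max": 19.6},
    "Mg": {"min": 1.0,   "median": 2.6,   "max": 7.5},
    "Ca": {"min": 2.7,   "median": 8.6,   "max": 34.9},
    "S":  {"min": 0.4,   "median": 1.5,   "max": 5.1},
    "B":  {"min": 0.011, "median": 0.038, "max": 0.105},
    "Cu": {"min": 0.001, "median": 0.008, "max": 0.036},
    "Zn": {"min": 0.006, "median": 0.018, "max": 0.129},
    "Mn": {"min": 0.066, "median": 0.964, "max": 4.954},
    "Fe": {"min": 0.002, "median": 0.076, "max": 0.594},
    "Fv": {"min": 925.6, "median": 952.1, "max": 973.3}
  }
}
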