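{
  "version": 1,
  "description": "Nutrient concentration compatibility intervals for young Eucalyptus: the state fertilization standards and the quartile (Q1, Q3) intervals of the 489 balanced high-yield (TN) survey specimens. Macronutrients in g/kg, micronutrients in mg/kg.",
  "state": {
    "provenance": "state standards",
    "bounds": {
      "N":  [15.0, 20.0],
      "P":  [1.0, 1.3],
      "K":  [9.0, 13.0],
      "Mg": [6.0, 10.0],
      "Ca": [5.0, 8.0],
      "S":  [1.5, 2.0],
      "B":  [30.0, 50.0],
      "Cu": [7.0, 10.0],
      "Zn": [35.0, 50.0],
      "Mn": [400.0, 600.0],
      "Fe": [150.0, 200.0]
    }
  },
  "tn_quartiles": {
    "provenance": "TN quartiles (0.25, 0.75), n=489",
    "bounds": {
      "N":  [17.0, 25.3],
      "P":  [1.0, 1.4],
      "K":  [7.2, 11.5],
      "Mg": [2.3, 3.2],
      "Ca": [7.0, 10.2],
      "S":  [1.2, 1.8],
      "B":  [6.0, 12.0],
      "Cu": [14.0, 21.0],
      "Zn": [60.0, 96.0],
      "Mn": [34.0, 54.0],
      "Fe": [679.0, 1281.0]
    }
  }
}
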