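{
  "version": 1,
  "description": "Two worked-example (fictive) foliar profiles used to contrast state-standard, quartile-interval, regional clr-index and local neighbor diagnoses. Macronutrients in g/kg, micronutrients in mg/kg.",
  "site1": {
    "N": 27.1, "P": 1.4, "K": 8.8, "Mg": 1.5, "Ca": 3.9, "S": 1.7,
    "B": 48.0, "Cu": 4.7, "Zn": 14.7, "Mn": 452.3, "Fe": 66.9
  },
  "site2": {
    "N": 15.0, "P": 1.3, "K": 8.2, "Mg": 3.8, "Ca": 21.2, "S": 1.4,
    "B": 1.3, "Cu": 17.9, "Zn": 151.8, "Mn": 73.8, "Fe": 1614.4
  }
}
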