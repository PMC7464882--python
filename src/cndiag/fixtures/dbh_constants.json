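{
  "version": 1,
  "description": "Diameter-at-breast-height constants: the economic high/low yield cutoff, the observed DBH of the two worked-example sites, the DBH of their successful local reference neighbors, and the floor used to screen successful neighbors.",
  "cutoff_cm": 4.3,
  "site_dbh_cm": {"site1": 4.06, "site2": 1.71},
  "neighbor_dbh_cm": [5.43, 5.44],
  "successful_floor_cm": 5.0
}
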