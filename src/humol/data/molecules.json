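{
  "_comment": "Reference molecule library for the four-component tissue model. Water and hydroxyapatite are exact stoichiometric formulas. Lipid and protein are representative elemental compositions: lipid is a long-chain triglyceride (triolein), protein a collagen/gelatin-like CHNOS mixture; both stand in for molecule classes, not single compounds.",
  "water": {
    "formula": "H2O"
  },
  "hydroxyapatite": {
    "formula": "Ca5(PO4)3(OH)",
    "notes": "bone mineral, Ca:P molar ratio 5:3"
  },
  "lipid": {
    "formula": "C57H104O6",
    "notes": "triolein, representative triglyceride"
  },
  "protein": {
    "mass_fractions": {
      "H": 0.066,
      "C": 0.502,
      "N": 0.175,
      "O": 0.250,
      "S": 0.007
    },
    "notes": "collagen/gelatin-like average composition"
  }
}
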