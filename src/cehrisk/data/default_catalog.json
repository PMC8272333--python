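{
  "h_plus": ["c2", "c3"],
  "er": ["c23", "c27", "c34", "c46", "c68", "c81", "c85", "c96", "c107"],
  "ap": ["c5", "c15", "c18", "c24", "c30", "c32", "c51", "c73"],
  "c1": ["c1"],
  "nonmhc_risk": {
    "d1": ["risk"],
    "d2": ["risk"],
    "d3": ["risk"]
  }
}
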