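{
  "_comment": "CAZy family -> cell-wall substrate groups. Editable config: family/substrate assignments drift with CAZy releases, so coverage beyond the seeded families is a config concern, not code.",
  "families": {
    "AA9": ["cellulose"],
    "GH9": ["cellulose"],
    "AA3": ["cellulose"],
    "GH31": ["hemicellulose"],
    "GH5_7": ["hemicellulose"],
    "GH29": ["hemicellulose"],
    "GH95": ["hemicellulose"],
    "AA1": ["lignin"],
    "AA1_2": ["lignin"],
    "AA2": ["lignin"],
    "GH35": ["pectin"],
    "GH2": ["pectin"],
    "PL1_7": ["pectin"],
    "GH28": ["pectin"],
    "CE4": ["chitin"],
    "GH18": ["chitin"],
    "GH92": ["mannan"],
    "GH125": ["mannan"],
    "GH76": ["mannan"],
    "CE17": ["mannan"],
    "GH151": ["other"]
  }
}
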