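{
  "_comment": "Default pathway definitions for hallmark-capability scoring. A role is satisfied when any of its alternatives is fully present; an alternative is a conjunction of EC numbers and/or CAZy family codes. Trailing '-' in an EC acts as a wildcard.",
  "pathways": [
    {
      "name": "cellulose_degradation",
      "roles": [
        {"name": "endoglucanase", "any_of": [["3.2.1.4"]]},
        {"name": "beta-glucosidase", "any_of": [["3.2.1.21"]]},
        {"name": "exoglucanase", "any_of": [["3.2.1.91"], ["3.2.1.176"]]}
      ]
    },
    {
      "name": "chitin_degradation",
      "roles": [
        {"name": "chitinase", "any_of": [["3.2.1.14"]]},
        {"name": "beta-N-acetylhexosaminidase", "any_of": [["3.2.1.52"]]},
        {"name": "chitin_deacetylase", "any_of": [["3.5.1.41"]]}
      ]
    },
    {
      "name": "thiamine_biosynthesis",
      "roles": [
        {"name": "thiamine_phosphate_synthase", "any_of": [["2.5.1.3"]]},
        {"name": "hydroxymethylpyrimidine_kinase", "any_of": [["2.7.1.49"]]}
      ]
    },
    {
      "name": "fatty_acid_synthesis",
      "roles": [
        {"name": "cytosolic_fatty_acid_synthase", "any_of": [["2.3.1.86"]]}
      ]
    },
    {
      "name": "vitamin_b6_metabolism",
      "roles": [
        {"name": "pyridoxine_kinase", "any_of": [["2.7.1.35"]]},
        {"name": "pyridoxamine_phosphate_oxidase", "any_of": [["1.4.3.5"]]},
        {"name": "pyridoxal_to_pyridoxine", "any_of": [
          ["1.1.1.65"],
          ["2.7.1.35", "1.4.3.5", "3.1.3.74"]
        ]}
      ]
    }
  ]
}
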