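{
  "methyl_pentofuranoside": {
    "C1": "Cf",
    "C2": "Cf",
    "C3": "Cf",
    "C4": "Cf",
    "C5": "Cg",
    "CH3": "Cg",
    "O4": "Of",
    "O1": "Os",
    "O2": "Oh",
    "O3": "Oh",
    "O5": "Oh",
    "H1": "H2",
    "H2": "H1",
    "H3": "H1",
    "H4": "H1",
    "H51": "H1",
    "H52": "H1",
    "H1M": "H1",
    "H2M": "H1",
    "H3M": "H1",
    "H2O": "Ho",
    "H3O": "Ho",
    "H5O": "Ho"
  }
}
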