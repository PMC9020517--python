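{
  "pnedd8": {
    "protein": "pNEDD8",
    "sequence": "nedd8",
    "residues": ["L2", "V5", "K6", "I13", "I15", "E18", "I26", "V30", "I44", "Y45", "K48", "E53", "T55", "K60", "L62", "L67", "H68"]
  },
  "pub": {
    "protein": "pUb",
    "sequence": "ubiquitin",
    "residues": ["I3", "V5", "K6", "T14", "L15", "E18", "K27", "D32", "I44", "F45", "Q49", "R54", "T55", "D58", "Q62", "T66", "L69"]
  },
  "nhpub": {
    "protein": "nhpUb",
    "sequence": "ubiquitin",
    "residues": ["I3", "V5", "K6", "T14", "L15", "E18", "K27", "D32", "I44", "F45", "L50", "R54", "T55", "D58", "Q62", "L69", "L71"]
  },
  "zz_panel": {
    "protein": "pNEDD8",
    "sequence": "nedd8",
    "residues": ["L2", "I13", "Y45", "T55", "L67", "H68"]
  }
}
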