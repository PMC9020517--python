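{
  "pnedd8": {
    "protein": "pNEDD8",
    "sequence": "nedd8",
    "residue_set": "pnedd8",
    "relaxed_fraction": 0.45,
    "k_conf": 8.3,
    "r1": 2.0,
    "noise_cv": 0.05,
    "ambiguous_residues": [21, 36, 47]
  },
  "pub": {
    "protein": "pUb",
    "sequence": "ubiquitin",
    "residue_set": "pub",
    "relaxed_fraction": 0.56,
    "k_conf": 2.0,
    "r1": 2.0,
    "noise_cv": 0.05,
    "ambiguous_residues": []
  },
  "nhpub": {
    "protein": "nhpUb",
    "sequence": "ubiquitin",
    "residue_set": "nhpub",
    "relaxed_fraction": 0.88,
    "k_conf": 2.0,
    "r1": 2.0,
    "noise_cv": 0.05,
    "ambiguous_residues": []
  }
}
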