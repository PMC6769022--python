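{
  "comment": "Physicochemical classes used to decompose buried interface area. The map is a calibration choice and is fully configurable; any recalibration should be recorded alongside results.",
  "classes": {
    "hydrophobic": ["ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY", "CYS"],
    "charged": ["ASP", "GLU", "LYS", "ARG"],
    "hydrophilic": ["SER", "THR", "ASN", "GLN", "TYR", "HIS"]
  }
}
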