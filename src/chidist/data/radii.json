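{
  "comment": "Van der Waals radii (angstrom) in the NACCESS tradition (Chothia 1976): N 1.65, O 1.40, S 1.85, trigonal/sp2 carbon 1.76, tetrahedral/sp3 carbon 1.87. Atoms are matched by name: backbone table first, then residue-specific sp2 carbons, then element defaults.",
  "backbone": {"N": 1.65, "CA": 1.87, "C": 1.76, "O": 1.40, "OXT": 1.40},
  "sp2_carbons": {
    "ARG": ["CZ"],
    "ASN": ["CG"],
    "ASP": ["CG"],
    "GLN": ["CD"],
    "GLU": ["CD"],
    "HIS": ["CG", "CD2", "CE1"],
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]
  },
  "sp2_carbon_radius": 1.76,
  "element_default": {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90},
  "fallback": 1.80
}
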