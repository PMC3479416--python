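{
  "comment": "Ideal bond lengths (angstrom) and bond angles (degrees) for sequential internal-coordinate construction of toy residues, Engh & Huber-style values. 'backbone' places N, CA, CB, C, O; 'side_chains' lists, per residue type, the chain of chi-placed atoms after CB as [name, bond_length_to_previous, bond_angle_with_two_previous].",
  "backbone": {
    "N_CA": 1.458,
    "CA_CB": 1.530,
    "CA_C": 1.525,
    "C_O": 1.231,
    "N_CA_CB": 110.5,
    "N_CA_C": 111.0,
    "CA_C_O": 120.5
  },
  "side_chains": {
    "SER": [["OG", 1.417, 110.8]],
    "THR": [["OG1", 1.433, 109.6]],
    "CYS": [["SG", 1.808, 114.4]],
    "VAL": [["CG1", 1.527, 110.5]],
    "PRO": [["CG", 1.495, 104.5], ["CD", 1.507, 106.1]],
    "ILE": [["CG1", 1.530, 110.4], ["CD1", 1.513, 113.8]],
    "LEU": [["CG", 1.530, 116.3], ["CD1", 1.521, 110.7]],
    "ASN": [["CG", 1.516, 112.7], ["OD1", 1.231, 120.8]],
    "ASP": [["CG", 1.516, 112.7], ["OD1", 1.249, 118.4]],
    "HIS": [["CG", 1.492, 113.8], ["ND1", 1.369, 122.7]],
    "PHE": [["CG", 1.502, 113.8], ["CD1", 1.384, 120.8]],
    "TYR": [["CG", 1.512, 113.9], ["CD1", 1.387, 120.8]],
    "TRP": [["CG", 1.498, 113.6], ["CD1", 1.365, 126.9]],
    "MET": [["CG", 1.520, 114.1], ["SD", 1.803, 112.7], ["CE", 1.791, 100.9]],
    "GLU": [["CG", 1.520, 114.1], ["CD", 1.516, 112.6], ["OE1", 1.249, 118.4]],
    "GLN": [["CG", 1.520, 114.1], ["CD", 1.516, 112.6], ["OE1", 1.231, 120.8]],
    "LYS": [["CG", 1.520, 114.1], ["CD", 1.520, 111.3], ["CE", 1.508, 111.9], ["NZ", 1.489, 111.7]],
    "ARG": [["CG", 1.520, 114.1], ["CD", 1.520, 111.3], ["NE", 1.461, 112.0], ["CZ", 1.329, 124.2]]
  }
}
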