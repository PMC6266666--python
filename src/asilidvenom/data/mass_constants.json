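{
  "comment": "Monoisotopic mass conventions, in daltons. Residue masses are the standard 20 canonical amino-acid residue (i.e. dehydrated) masses to 5 decimal places. Modification deltas: a disulfide bond removes two hydrogens; N-terminal pyroglutamate formation from Gln loses NH3; reduction restores one hydrogen per cysteine; hydroxyethyl alkylation (iodoethanol) adds C2H4O per cysteine.",
  "residue_masses": {
    "A": 71.03711,
    "C": 103.00918,
    "D": 115.02694,
    "E": 129.04259,
    "F": 147.06841,
    "G": 57.02146,
    "H": 137.05891,
    "I": 113.08406,
    "K": 128.09496,
    "L": 113.08406,
    "M": 131.04048,
    "N": 114.04293,
    "P": 97.05276,
    "Q": 128.05858,
    "R": 156.10111,
    "S": 87.03203,
    "T": 101.04768,
    "V": 99.06841,
    "W": 186.07931,
    "Y": 163.06333
  },
  "water_mass": 18.01056,
  "proton_mass": 1.00728,
  "delta_disulfide_per_bond": -2.01566,
  "delta_pyroglu": -17.02655,
  "delta_hydroxyethyl_per_cys": 44.02621,
  "delta_reduction_per_cys": 1.00783
}
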