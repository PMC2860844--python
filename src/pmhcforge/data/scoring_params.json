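{
 "lj": {
  "C": {"radius": 1.7, "eps": 0.1},
  "N": {"radius": 1.55, "eps": 0.16},
  "O": {"radius": 1.52, "eps": 0.2},
  "S": {"radius": 1.8, "eps": 0.25}
 },
 "hbond": {"r0": 2.9, "eps": 2.0},
 "coulomb_k": 332.06,
 "dielectric": {"mode": "distance", "factor": 4.0, "constant": 80.0},
 "cutoff": 8.0,
 "torsion_k": 0.5,
 "charges": {
  "LYS": {"NZ": 1.0},
  "ARG": {"CZ": 1.0},
  "ASP": {"OD1": -0.5, "OD2": -0.5},
  "GLU": {"OE1": -0.5, "OE2": -0.5},
  "HIS": {"ND1": 0.05, "NE2": 0.05}
 },
 "terminus_charge": 1.0
}
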