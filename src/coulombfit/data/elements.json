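{
  "H":  {"Z": 1,  "mass": 1.008},
  "D":  {"Z": 1,  "mass": 2.014101778},
  "He": {"Z": 2,  "mass": 4.002602},
  "Li": {"Z": 3,  "mass": 6.94},
  "Be": {"Z": 4,  "mass": 9.0121831},
  "B":  {"Z": 5,  "mass": 10.81},
  "C":  {"Z": 6,  "mass": 12.011},
  "N":  {"Z": 7,  "mass": 14.007},
  "O":  {"Z": 8,  "mass": 15.999},
  "F":  {"Z": 9,  "mass": 18.998403163},
  "Ne": {"Z": 10, "mass": 20.1797},
  "Na": {"Z": 11, "mass": 22.98976928},
  "Mg": {"Z": 12, "mass": 24.305},
  "Al": {"Z": 13, "mass": 26.9815384},
  "Si": {"Z": 14, "mass": 28.085},
  "P":  {"Z": 15, "mass": 30.973761998},
  "S":  {"Z": 16, "mass": 32.06},
  "Cl": {"Z": 17, "mass": 35.45},
  "Ar": {"Z": 18, "mass": 39.948}
}
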