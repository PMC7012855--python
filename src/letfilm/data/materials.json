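{
  "_comment": "Material registry, version 1. Film compositions are ATOMIC percent as stated by the manufacturer; densities of the films' active layers are a typical manufacturer value (not critical: all headline ratios are density-independent). I_override in eV where a compound value is standard.",
  "materials": {
    "EBT3_active": {
      "composition": {"H": 56.5, "Li": 0.6, "C": 27.4, "N": 0.3, "O": 13.3, "Na": 0.1, "Al": 1.6, "S": 0.1, "Cl": 0.1},
      "density": 1.20
    },
    "EBT3_overall": {
      "composition": {"H": 38.4, "Li": 0.1, "C": 43.7, "N": 0.0, "O": 17.7, "Na": 0.0, "Al": 0.2, "S": 0.0, "Cl": 0.0},
      "density": 1.35
    },
    "MDV3_active": {
      "composition": {"H": 58.2, "Li": 0.6, "C": 27.7, "N": 0.4, "O": 11.7, "Na": 0.5, "Al": 0.3, "S": 0.1, "Cl": 0.6},
      "density": 1.20
    },
    "MDV3_overall": {
      "composition": {"H": 38.3, "Li": 0.0, "C": 43.9, "N": 0.0, "O": 17.7, "Na": 0.0, "Al": 0.0, "S": 0.0, "Cl": 0.0},
      "density": 1.35
    },
    "water": {
      "composition": {"H": 2, "O": 1},
      "density": 1.0,
      "I_override": 75.0
    },
    "aluminium": {
      "composition": {"Al": 1},
      "density": 2.699,
      "I_override": 166.0
    },
    "PMMA": {
      "composition": {"H": 8, "C": 5, "O": 2},
      "density": 1.19,
      "I_override": 74.0
    }
  }
}
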