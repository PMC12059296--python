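{
  "_version": "1.0",
  "_comment": "Barrier and target materials. Density in g/cm^3; composition maps element symbol to mass fraction as tabulated. Lead is not in the tabulated material list (it enters only through fitted transmission parameters); it is added here as elemental Pb at the standard 11.35 g/cm^3 and flagged tabulated=false.",
  "materials": {
    "air": {
      "display": "Air",
      "density": 0.001205,
      "composition": {"N": 0.755268, "O": 0.231781, "Ar": 0.012827, "C": 0.000124},
      "tabulated": true,
      "aliases": []
    },
    "glass": {
      "display": "Glass",
      "density": 2.5,
      "composition": {"Na": 0.1020, "Ca": 0.0510, "Si": 0.2480, "O": 0.5990},
      "tabulated": true,
      "aliases": []
    },
    "lw_concrete": {
      "display": "LW concrete",
      "density": 1.6,
      "composition": {"H": 0.01, "C": 0.001, "O": 0.529107, "Na": 0.016, "Mg": 0.002, "Al": 0.033872, "Si": 0.337021, "K": 0.013, "Ca": 0.044, "Fe": 0.014},
      "tabulated": true,
      "aliases": ["lw concrete", "lightweight concrete", "light-weight concrete", "concrete lw"]
    },
    "nw_concrete": {
      "display": "NW concrete",
      "density": 2.3,
      "composition": {"H": 0.01, "C": 0.001, "O": 0.529107, "Na": 0.016, "Mg": 0.002, "Al": 0.033872, "Si": 0.337021, "K": 0.013, "Ca": 0.044, "Fe": 0.014},
      "tabulated": true,
      "aliases": ["nw concrete", "normal-weight concrete", "normal weight concrete", "concrete", "concrete nw"]
    },
    "a514_steel": {
      "display": "A514 steel",
      "density": 7.85,
      "composition": {"Fe": 0.97, "Mn": 0.0095, "Cr": 0.0065, "Si": 0.006, "Mo": 0.0023, "C": 0.004675, "Zr": 0.001, "B": 0.000025},
      "tabulated": true,
      "aliases": ["514 steel", "steel", "a514", "514steel"]
    },
    "gypsum": {
      "display": "Gypsum",
      "density": 2.33,
      "composition": {"H": 0.0234, "O": 0.55757, "S": 0.186218, "Ca": 0.23279},
      "tabulated": true,
      "aliases": ["wallboard", "drywall"]
    },
    "muscle": {
      "display": "Muscle",
      "density": 1.05,
      "composition": {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.71, "Na": 0.001, "P": 0.002, "S": 0.003, "Cl": 0.001, "K": 0.004},
      "tabulated": true,
      "aliases": ["tissue", "soft tissue"]
    },
    "lead": {
      "display": "Lead",
      "density": 11.35,
      "composition": {"Pb": 1.0},
      "tabulated": false,
      "aliases": ["pb"]
    }
  }
}
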