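{
  "_version": "1.0",
  "_comment": "Physical constants of the four supported radionuclides. gamma_constant is the exposure-rate constant at 1 cm in R*cm^2/(mCi*h); f_factor converts exposure to tissue absorbed dose in cGy/R; photon_lines are [energy_keV, yield_per_decay] for the dominant emissions above 15 keV and 100 ppm abundance. ss_* columns are the Smith & Stabin lead value layers, carried for comparison only.",
  "nuclides": {
    "Tc-99m": {
      "half_life": 6.02,
      "half_life_unit": "h",
      "decay_mode": "isomeric transition",
      "gamma_constant": 0.795,
      "f_factor": 0.959,
      "photon_lines": [[140.0, 0.8907]],
      "ss_hvl_lead_mm": 0.234,
      "ss_tvl_lead_mm": 0.905,
      "aliases": ["tc99m", "99mtc", "technetium99m"]
    },
    "I-131": {
      "half_life": 8.02,
      "half_life_unit": "d",
      "decay_mode": "beta-",
      "gamma_constant": 2.2,
      "f_factor": 0.963,
      "photon_lines": [[364.0, 0.812], [637.0, 0.0726]],
      "ss_hvl_lead_mm": 2.74,
      "ss_tvl_lead_mm": 9.93,
      "aliases": ["i131", "131i", "iodine131"]
    },
    "Lu-177": {
      "half_life": 6.65,
      "half_life_unit": "d",
      "decay_mode": "beta-",
      "gamma_constant": 0.181,
      "f_factor": 0.957,
      "photon_lines": [[113.0, 0.06], [208.0, 0.11]],
      "ss_hvl_lead_mm": 0.542,
      "ss_tvl_lead_mm": 2.11,
      "aliases": ["lu177", "177lu", "lutetium177"]
    },
    "F-18": {
      "half_life": 109.8,
      "half_life_unit": "min",
      "decay_mode": "beta+, EC",
      "gamma_constant": 5.7,
      "f_factor": 0.876,
      "photon_lines": [[511.0, 1.94]],
      "ss_hvl_lead_mm": 4.95,
      "ss_tvl_lead_mm": 15.1,
      "aliases": ["f18", "18f", "fluorine18"]
    }
  }
}
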