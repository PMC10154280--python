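{
  "kinetics": [
    {"species": "Cyanidium caldarium", "Sc_o": 224.6, "Kc_uM": 6.7, "Ko_uM": 374.0, "T_ref_C": 25.0},
    {"species": "Galdieria partita", "Sc_o": 238.1, "Kc_uM": 6.6, "Ko_uM": 374.0, "T_ref_C": 25.0},
    {"species": "Galdieria sulphuraria", "Sc_o": 166.0, "Kc_uM": 3.3, "Ko_uM": 374.0, "T_ref_C": 25.0}
  ],
  "q10": {
    "q10_sco_25": 0.60,
    "q10_sco_35": 0.62,
    "q10_kc_ubar": 2.24,
    "q10_ko_mbar": 1.63
  },
  "rl_vcmax_ratio": {"40": 0.13, "30": 0.07},
  "dissolved_o2_uM": [
    {"o2_percent": 2, "temperature_c": 40, "o_uM": 20.0},
    {"o2_percent": 21, "temperature_c": 40, "o_uM": 209.0},
    {"o2_percent": 40, "temperature_c": 40, "o_uM": 398.0},
    {"o2_percent": 21, "temperature_c": 30, "o_uM": 251.0}
  ]
}
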