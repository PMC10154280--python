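{
  "source": "CRC Handbook pure-water density, 0-50 degC, 5 degC steps, kg/L",
  "temperature_c": [0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50],
  "density_kg_per_l": [0.99984, 0.99996, 0.99970, 0.99910, 0.99821,
                       0.99705, 0.99565, 0.99403, 0.99222, 0.99022, 0.98804],
  "quadratic_coefficients": [-4.97249417e-06, 6.62470862e-06, 1.00000531e+00],
  "valid_range_c": [0, 50]
}
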