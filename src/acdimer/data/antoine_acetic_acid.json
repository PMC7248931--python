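{
  "compound": "acetic acid",
  "A": 4.68206,
  "B": 1642.54,
  "C": -39.764,
  "T_min_K": 290.26,
  "T_max_K": 391.01,
  "pressure_unit": "bar",
  "log_convention": "log10",
  "source": "NIST Chemistry WebBook Antoine parameters (Stull 1947 compilation), log10(p/bar) = A - B/(T/K + C)"
}
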