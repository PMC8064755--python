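{
  "version": 1,
  "description": "KaiC phosphoform interconversion rate constants measured in vitro (Rust et al., Science 2007, Table S1). Rate law: k_XY(A) = k0 + kA * A / (K_half + A), units hr^-1; A is the active KaiA concentration in uM.",
  "K_half_uM": 0.43,
  "C_tot_uM": 3.4,
  "kaiA_total_uM": 1.3,
  "rates": {
    "UT": {"k0": 0.0,  "kA": 0.479077},
    "TU": {"k0": 0.21, "kA": 0.0798462},
    "TD": {"k0": 0.0,  "kA": 0.212923},
    "DT": {"k0": 0.0,  "kA": 0.173},
    "DS": {"k0": 0.31, "kA": -0.319385},
    "SD": {"k0": 0.0,  "kA": 0.505692},
    "SU": {"k0": 0.11, "kA": -0.133077},
    "US": {"k0": 0.0,  "kA": 0.0532308}
  }
}
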