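{
  "comment": "Package default heptad propensity table (Lupas-style: hydrophobics favored at a/d, charged at e/g) and window-score Gaussians for the coiled-coil vs globular decision. Versioned with the package; not a digit-level copy of any published table.",
  "version": 1,
  "window": 21,
  "gauss_cc": [1.63, 0.24],
  "gauss_glob": [0.77, 0.20],
  "p_cutoff": 0.5,
  "min_run": 14,
  "propensities": {
    "L": [3.2, 0.45, 0.45, 3.9, 0.45, 0.5, 0.5],
    "I": [2.2, 0.4, 0.4, 1.9, 0.35, 0.4, 0.4],
    "V": [1.2, 0.5, 0.5, 1.3, 0.5, 0.5, 0.5],
    "M": [2.2, 0.6, 0.6, 1.5, 0.6, 0.6, 0.6],
    "F": [0.9, 0.4, 0.4, 1.0, 0.4, 0.4, 0.4],
    "A": [1.3, 0.9, 0.9, 1.1, 0.9, 0.9, 0.9],
    "E": [0.5, 1.2, 1.1, 0.4, 1.6, 1.0, 1.3],
    "K": [0.5, 1.1, 1.0, 0.4, 1.4, 1.0, 1.3],
    "Q": [0.6, 1.2, 1.1, 0.5, 1.4, 1.0, 1.2],
    "R": [0.6, 1.0, 1.0, 0.5, 1.2, 0.9, 1.1],
    "D": [0.4, 0.9, 0.9, 0.35, 0.9, 0.9, 0.8],
    "N": [0.5, 0.9, 0.9, 0.45, 0.9, 0.9, 0.8],
    "S": [0.6, 0.8, 0.8, 0.5, 0.8, 0.8, 0.8],
    "T": [0.6, 0.8, 0.8, 0.55, 0.8, 0.8, 0.8],
    "H": [0.5, 0.8, 0.8, 0.5, 0.8, 0.8, 0.8],
    "G": [0.3, 0.6, 0.6, 0.3, 0.6, 0.6, 0.6],
    "P": [0.05, 0.15, 0.15, 0.05, 0.15, 0.15, 0.15],
    "C": [0.6, 0.5, 0.5, 0.6, 0.5, 0.5, 0.5],
    "W": [0.5, 0.4, 0.4, 0.5, 0.4, 0.4, 0.4],
    "Y": [0.6, 0.5, 0.5, 0.6, 0.5, 0.5, 0.5]
  }
}
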