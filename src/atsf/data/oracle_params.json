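{
  "version": 1,
  "description": "Synthetic conformation-dependent charge oracle for typed furanosides. Charges are base(type) + alpha * s(type_i) * sum_j s(type_j) exp(-R_ij / rho), with aliphatic hydrogens (H1, H2) clamped to zero and the residual spread uniformly over the remaining atoms. Constants are frozen artifact values chosen once: bases mimic carbohydrate force-field charge scales, couplings are concentrated on oxygen-bearing groups so the conformational signal rides mostly on hydroxyl/ring-oxygen distances and varies on the ~0.01-0.1 e scale.",
  "rho": 1.25,
  "alpha": 0.35,
  "base": {
    "Cf": 0.28,
    "Cg": 0.17,
    "Of": -0.42,
    "Os": -0.40,
    "Oh": -0.66,
    "Ho": 0.43,
    "H1": 0.0,
    "H2": 0.0
  },
  "sensitivity": {
    "Cf": 0.05,
    "Cg": 0.05,
    "Of": -0.5,
    "Os": -0.5,
    "Oh": -0.6,
    "Ho": 0.55,
    "H1": 0.03,
    "H2": 0.03
  },
  "clamped_types": ["H1", "H2"]
}
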