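{
  "name": "ar",
  "description": "Androgen receptor activity score: 20 AR-regulated genes, z-scored per gene and averaged (mean of z-scores; equals the summed form up to scale at full coverage).",
  "normalization": "zscore",
  "combination": "mean",
  "min_fraction": 0.5,
  "components": [
    {"gene": "KLK3", "aliases": ["PSA"], "direction": 1, "weight": 1.0},
    {"gene": "KLK2", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "PMEPA1", "aliases": ["TMEPAI"], "direction": 1, "weight": 1.0},
    {"gene": "ABCC4", "aliases": ["MRP4"], "direction": 1, "weight": 1.0},
    {"gene": "NKX3-1", "aliases": ["NKX3.1"], "direction": 1, "weight": 1.0},
    {"gene": "C1orf116", "aliases": ["SARG"], "direction": 1, "weight": 1.0},
    {"gene": "FKBP5", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "ACSL3", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "ZBTB10", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "HERC3", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "PTGER4", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "MPHOSPH9", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "EAF2", "aliases": ["U19"], "direction": 1, "weight": 1.0},
    {"gene": "MED28", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "NNMT", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "MAF", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "GNMT", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "ADAM7", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "ELL2", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "TMPRSS2", "aliases": [], "direction": 1, "weight": 1.0}
  ]
}
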