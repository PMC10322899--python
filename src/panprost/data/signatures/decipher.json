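{
  "name": "decipher",
  "description": "Genomic classifier for metastatic progression, 20 markers (research reconstruction; published descriptions vary between 17 and 22 usable markers depending on platform coverage). Score = mean across-sample percentile of risk-up markers minus mean percentile of risk-down markers.",
  "normalization": "percentile",
  "combination": "signed_percentile_mean",
  "min_fraction": 0.5,
  "components": [
    {"gene": "UBE2C", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "NUSAP1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "ZWILCH", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "CAMK2N1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "RABGAP1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "PBX1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "NFIB", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "IQGAP3", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "LASP1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "THBS2", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "PCAT-32", "aliases": ["PCAT32"], "direction": 1, "weight": 1.0},
    {"gene": "PCAT-80", "aliases": ["PCAT80", "GLYATL1P4"], "direction": 1, "weight": 1.0},
    {"gene": "ANO7", "aliases": ["PDRG2"], "direction": -1, "weight": 1.0},
    {"gene": "EPPK1", "aliases": [], "direction": -1, "weight": 1.0},
    {"gene": "MYBPC1", "aliases": [], "direction": -1, "weight": 1.0},
    {"gene": "PCDH7", "aliases": [], "direction": -1, "weight": 1.0},
    {"gene": "S1PR4", "aliases": ["EDG6"], "direction": -1, "weight": 1.0},
    {"gene": "TNFRSF19", "aliases": ["TROY"], "direction": -1, "weight": 1.0},
    {"gene": "TSBP1", "aliases": ["C6orf10"], "direction": -1, "weight": 1.0},
    {"gene": "PCAT-104", "aliases": ["PCAT104"], "direction": -1, "weight": 1.0}
  ]
}
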