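{
  "name": "oncotype_dx",
  "description": "12-gene genomic prostate score (research reconstruction): four gene groups (androgen signaling, cellular organization, proliferation, stromal response), each averaged then linearly combined with published group weights. Output is on an arbitrary linear scale, not the commercial 0-100 GPS scale.",
  "normalization": "center",
  "combination": "grouped_linear",
  "min_fraction": 0.5,
  "group_weights": {
    "androgen": -0.352,
    "cellular_organization": -0.368,
    "proliferation": 0.095,
    "stromal_response": 0.735
  },
  "components": [
    {"gene": "AZGP1", "aliases": [], "direction": 1, "weight": 1.0, "group": "androgen"},
    {"gene": "FAM13C", "aliases": [], "direction": 1, "weight": 1.0, "group": "androgen"},
    {"gene": "KLK2", "aliases": [], "direction": 1, "weight": 1.0, "group": "androgen"},
    {"gene": "SRD5A2", "aliases": [], "direction": 1, "weight": 1.0, "group": "androgen"},
    {"gene": "FLNC", "aliases": [], "direction": 1, "weight": 1.0, "group": "cellular_organization"},
    {"gene": "GSN", "aliases": [], "direction": 1, "weight": 1.0, "group": "cellular_organization"},
    {"gene": "GSTM2", "aliases": [], "direction": 1, "weight": 1.0, "group": "cellular_organization"},
    {"gene": "TPM2", "aliases": [], "direction": 1, "weight": 1.0, "group": "cellular_organization"},
    {"gene": "TPX2", "aliases": [], "direction": 1, "weight": 1.0, "group": "proliferation"},
    {"gene": "BGN", "aliases": [], "direction": 1, "weight": 1.0, "group": "stromal_response"},
    {"gene": "COL1A1", "aliases": [], "direction": 1, "weight": 1.0, "group": "stromal_response"},
    {"gene": "SFRP4", "aliases": [], "direction": 1, "weight": 1.0, "group": "stromal_response"}
  ]
}
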