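{
  "name": "prolaris",
  "description": "Cell-cycle progression (CCP) risk score, 34 genes (research reconstruction of the published panel): per-gene centered log2 expression averaged across the panel. The commercial assay additionally normalizes against housekeeping genes, which is out of scope here.",
  "normalization": "center",
  "combination": "mean",
  "min_fraction": 0.5,
  "components": [
    {"gene": "FOXM1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "CDC20", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "CDKN3", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "CDK1", "aliases": ["CDC2"], "direction": 1, "weight": 1.0},
    {"gene": "KIF11", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "PCLAF", "aliases": ["KIAA0101"], "direction": 1, "weight": 1.0},
    {"gene": "NUSAP1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "CENPF", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "ASPM", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "BUB1B", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "RRM2", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "DLGAP5", "aliases": ["DLG7"], "direction": 1, "weight": 1.0},
    {"gene": "BIRC5", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "KIF20A", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "PLK1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "TOP2A", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "TK1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "PBK", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "ASF1B", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "SKA1", "aliases": ["C18orf24"], "direction": 1, "weight": 1.0},
    {"gene": "RAD54L", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "PTTG1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "CDCA3", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "MCM10", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "PRC1", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "DTL", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "CEP55", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "RAD51", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "CENPM", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "CDCA8", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "ORC6", "aliases": ["ORC6L"], "direction": 1, "weight": 1.0},
    {"gene": "KIF2C", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "CDCA2", "aliases": [], "direction": 1, "weight": 1.0},
    {"gene": "MKI67", "aliases": [], "direction": 1, "weight": 1.0}
  ]
}
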