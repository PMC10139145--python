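{
  "comment": "Core tear-protein library: melting temperatures (degC) of the five major tear proteins measured individually by nanoDSF, a shared van't Hoff enthalpy default (kJ/mol), and ligand-induced Tm shifts at saturating ligand (100 uM myristic acid; 1 mM Fe(III) citrate). Emission coefficients are model defaults shared by all species.",
  "emission_defaults": {
    "a330": 1.0,
    "a350": 1.0,
    "d330": -0.01,
    "d350": 0.01,
    "baseline_slope_330": 0.0,
    "baseline_slope_350": 0.0
  },
  "dh_vanthoff_default": 800.0,
  "species": {
    "LYZ": {"tm_celsius": 67.8, "full_name": "lysozyme C"},
    "LCN1": {"tm_celsius": 69.4, "full_name": "lipocalin-1"},
    "IGA": {"tm_celsius": 72.9, "full_name": "immunoglobulin A"},
    "HSA": {"tm_celsius": 75.1, "full_name": "serum albumin"},
    "LTF": {"tm_celsius": 67.4, "full_name": "lactotransferrin"}
  },
  "ligands": {
    "MYRISTATE": {"set": {"HSA": 80.3, "LYZ": 55.6}},
    "FE3": {"set": {"LTF": 95.0}},
    "LATANOPROST": {"set": {}}
  },
  "mixtures": {
    "CONTROL": {"HSA": 140.0, "LTF": 110.0, "LYZ": 50.0, "IGA": 30.0, "LCN1": 100.0},
    "POAG": {"HSA": 110.0, "LTF": 150.0, "LYZ": 30.0, "IGA": 30.0, "LCN1": 60.0}
  }
}
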