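{
  "version": "bmfqsar-mlfer-s-synthetic-1.0",
  "note": "SYNTHETIC stand-in table. Follows the group-contribution form of the Platts et al. fragment scheme for the Abraham dipolarity/polarizability descriptor S (intercept + sum of SMARTS-fragment counts x coefficients), but the coefficient values are package-local calibrations, not the published ones, which are not redistributable here. Counts use unique RDKit substructure matches.",
  "intercept": 0.277,
  "fragments": [
    {"label": "aromatic carbon", "smarts": "[c]", "coefficient": 0.068},
    {"label": "aromatic nitrogen", "smarts": "[n]", "coefficient": 0.32},
    {"label": "sp2 carbon (non-aromatic)", "smarts": "[C;^2]", "coefficient": 0.05},
    {"label": "sp carbon", "smarts": "[C;^1]", "coefficient": 0.1},
    {"label": "hydroxyl", "smarts": "[OX2H]", "coefficient": 0.247},
    {"label": "ether/ester oxygen", "smarts": "[OX2H0]", "coefficient": 0.154},
    {"label": "carbonyl", "smarts": "[CX3]=[OX1]", "coefficient": 0.334},
    {"label": "nitro", "smarts": "[N+](=O)[O-]", "coefficient": 0.4},
    {"label": "nitrile", "smarts": "C#N", "coefficient": 0.55},
    {"label": "amine nitrogen", "smarts": "[NX3;!$(N=O);!$(N[+])]", "coefficient": 0.21},
    {"label": "thioether/thiol sulfur", "smarts": "[SX2]", "coefficient": 0.29},
    {"label": "sulfoxide/sulfone sulfur", "smarts": "[SX3,SX4]", "coefficient": 0.72},
    {"label": "fluorine", "smarts": "[F]", "coefficient": -0.02},
    {"label": "chlorine", "smarts": "[Cl]", "coefficient": 0.071},
    {"label": "bromine", "smarts": "[Br]", "coefficient": 0.141},
    {"label": "iodine", "smarts": "[I]", "coefficient": 0.211},
    {"label": "siloxane silicon", "smarts": "[Si]", "coefficient": -0.12},
    {"label": "phosphate phosphorus", "smarts": "[P]", "coefficient": 0.4}
  ]
}
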