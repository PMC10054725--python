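{
  "version": "bmfqsar-atom-properties-1.0",
  "source": "standard atomic weights (IUPAC 2021 abridged) and NIST first ionization energies",
  "mass": {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078,
    "Zn": 65.38, "As": 74.922, "Se": 78.971, "Br": 79.904, "Sn": 118.71,
    "I": 126.904, "Hg": 200.592
  },
  "ionization_eV": {
    "H": 13.598, "B": 8.298, "C": 11.260, "N": 14.534, "O": 13.618,
    "F": 17.423, "Na": 5.139, "Mg": 7.646, "Al": 5.986, "Si": 8.152,
    "P": 10.487, "S": 10.360, "Cl": 12.968, "K": 4.341, "Ca": 6.113,
    "Zn": 9.394, "As": 9.815, "Se": 9.752, "Br": 11.814, "Sn": 7.344,
    "I": 10.451, "Hg": 10.438
  },
  "valence_electrons": {
    "H": 1, "B": 3, "C": 4, "N": 5, "O": 6, "F": 7, "Na": 1, "Mg": 2,
    "Al": 3, "Si": 4, "P": 5, "S": 6, "Cl": 7, "K": 1, "Ca": 2, "Zn": 2,
    "As": 5, "Se": 6, "Br": 7, "Sn": 4, "I": 7, "Hg": 2
  }
}
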