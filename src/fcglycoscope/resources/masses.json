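{
  "version": "1.0",
  "comment": "Monoisotopic masses in Da. Residue masses are dehydrated amino-acid residues; monosaccharide masses are dehydrated glycosyl residues (glycosidic-bond convention: attachment adds no water).",
  "residues": {
    "G": 57.0214637,
    "A": 71.0371138,
    "S": 87.0320284,
    "P": 97.0527638,
    "V": 99.0684139,
    "T": 101.0476785,
    "C": 103.0091844,
    "L": 113.0840640,
    "I": 113.0840640,
    "N": 114.0429274,
    "D": 115.0269430,
    "Q": 128.0585775,
    "K": 128.0949630,
    "E": 129.0425931,
    "M": 131.0404846,
    "H": 137.0589119,
    "F": 147.0684139,
    "R": 156.1011110,
    "Y": 163.0633285,
    "W": 186.0793129
  },
  "water": 18.0105646,
  "proton": 1.00727646,
  "electron": 0.00054858,
  "modifications": {
    "carbamidomethyl": 57.0214637,
    "oxidation": 15.9949146,
    "acetyl": 42.0105646,
    "deamidation": 0.9840156,
    "deamidation_18O": 2.9882620
  },
  "monosaccharides": {
    "HexNAc": 203.0793725,
    "Hex": 162.0528234,
    "Fuc": 146.0579088,
    "NeuAc": 291.0954165
  }
}
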