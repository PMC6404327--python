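{
 "scenario": "M1",
 "groups": [
  {
   "label": "A",
   "codons": [
    "AAA",
    "AAT",
    "AAG",
    "AAC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "C",
   "codons": [
    "CGA",
    "CGT",
    "CGG",
    "CGC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "D",
   "codons": [
    "ACA",
    "ACT",
    "ACG",
    "ACC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "E",
   "codons": [
    "GTA",
    "GTT",
    "GTG",
    "GTC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "F",
   "codons": [
    "CAA",
    "CAT",
    "CAG",
    "CAC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "G",
   "codons": [
    "AGA",
    "AGT",
    "AGG",
    "AGC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "H",
   "codons": [
    "CCA",
    "CCT",
    "CCG",
    "CCC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "I",
   "codons": [
    "ATA",
    "ATT",
    "ATG",
    "ATC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "K",
   "codons": [
    "CTA",
    "CTT",
    "CTG",
    "CTC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "L",
   "codons": [
    "TAA",
    "TAT",
    "TAG",
    "TAC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "M",
   "codons": [
    "GCA",
    "GCT",
    "GCG",
    "GCC"
   ],
   "psi": 1.0,
   "phi_printed": "2/3"
  },
  {
   "label": "N",
   "codons": [
    "TCG",
    "TCC"
   ],
   "psi": 1.0,
   "phi_printed": "8/9"
  },
  {
   "label": "P",
   "codons": [
    "TCA",
    "TCT"
   ],
   "psi": 1.0,
   "phi_printed": "8/9"
  },
  {
   "label": "Q",
   "codons": [
    "TTA",
    "TTG"
   ],
   "psi": 1.0,
   "phi_printed": "8/9"
  },
  {
   "label": "R",
   "codons": [
    "TTT",
    "TTC"
   ],
   "psi": 1.0,
   "phi_printed": "8/9"
  },
  {
   "label": "S",
   "codons": [
    "TGT",
    "TGC"
   ],
   "psi": 0.8648035,
   "phi_printed": "8/9"
  },
  {
   "label": "T",
   "codons": [
    "TGA",
    "TGG"
   ],
   "psi": 0.864803,
   "phi_printed": "8/9"
  },
  {
   "label": "V",
   "codons": [
    "GAT",
    "GAC"
   ],
   "psi": 0.8344635,
   "phi_printed": "8/9"
  },
  {
   "label": "W",
   "codons": [
    "GAA",
    "GAG"
   ],
   "psi": 0.834463,
   "phi_printed": "8/9"
  },
  {
   "label": "Y",
   "codons": [
    "GGG",
    "GGC"
   ],
   "psi": 0.6446255,
   "phi_printed": "8/9"
  },
  {
   "label": "*",
   "codons": [
    "GGA",
    "GGT"
   ],
   "psi": 0.644625,
   "phi_printed": "8/9"
  }
 ]
}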