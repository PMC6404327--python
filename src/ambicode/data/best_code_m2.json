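{
 "scenario": "M2",
 "groups": [
  {
   "label": "A",
   "codons": [
    "CAT",
    "CAG",
    "CAC",
    "CTG",
    "CGG",
    "CCG"
   ],
   "psi": 0.9867038,
   "phi_printed": "36/54"
  },
  {
   "label": "C",
   "codons": [
    "CAA",
    "CTA",
    "CTT",
    "CTC",
    "CGA",
    "CCA"
   ],
   "psi": 0.9866648,
   "phi_printed": "35/54"
  },
  {
   "label": "D",
   "codons": [
    "GAG",
    "GAC",
    "GGC",
    "GCC"
   ],
   "psi": 1.0,
   "phi_printed": "7/9"
  },
  {
   "label": "E",
   "codons": [
    "GAA",
    "GGA",
    "GGG",
    "GCA"
   ],
   "psi": 1.0,
   "phi_printed": "7/9"
  },
  {
   "label": "F",
   "codons": [
    "GAT",
    "GTT",
    "GTG",
    "GCT"
   ],
   "psi": 0.8262542,
   "phi_printed": "7/9"
  },
  {
   "label": "G",
   "codons": [
    "GTA",
    "GTC",
    "GGT",
    "GCG"
   ],
   "psi": 0.783784,
   "phi_printed": "34/36"
  },
  {
   "label": "H",
   "codons": [
    "ATC",
    "AGC",
    "ACC",
    "CCT"
   ],
   "psi": 0.6426162,
   "phi_printed": "5/6"
  },
  {
   "label": "I",
   "codons": [
    "ATT",
    "AGT",
    "ACT"
   ],
   "psi": 0.8457703,
   "phi_printed": "7/9"
  },
  {
   "label": "K",
   "codons": [
    "ATA",
    "AGA",
    "ACA"
   ],
   "psi": 0.813687,
   "phi_printed": "7/9"
  },
  {
   "label": "L",
   "codons": [
    "AAT",
    "AAG",
    "AGG"
   ],
   "psi": 0.7359857,
   "phi_printed": "23/27"
  },
  {
   "label": "M",
   "codons": [
    "AAA",
    "AAC",
    "CGC"
   ],
   "psi": 0.7170777,
   "phi_printed": "25/27"
  },
  {
   "label": "N",
   "codons": [
    "TAA",
    "TAC",
    "TTC"
   ],
   "psi": 0.5927813,
   "phi_printed": "23/27"
  },
  {
   "label": "P",
   "codons": [
    "TCT",
    "TCG",
    "CCC"
   ],
   "psi": 0.559873,
   "phi_printed": "25/27"
  },
  {
   "label": "Q",
   "codons": [
    "TTA",
    "TCA",
    "CGT"
   ],
   "psi": 0.49327,
   "phi_printed": "25/27"
  },
  {
   "label": "R",
   "codons": [
    "ATG",
    "ACG"
   ],
   "psi": 0.8650405,
   "phi_printed": "8/9"
  },
  {
   "label": "S",
   "codons": [
    "TAT",
    "TAG"
   ],
   "psi": 0.8027995,
   "phi_printed": "8/9"
  },
  {
   "label": "T",
   "codons": [
    "TTT",
    "TGT"
   ],
   "psi": 0.7850055,
   "phi_printed": "8/9"
  },
  {
   "label": "V",
   "codons": [
    "TGC",
    "TCC"
   ],
   "psi": 0.7838025,
   "phi_printed": "8/9"
  },
  {
   "label": "W",
   "codons": [
    "TGA"
   ],
   "psi": 1.0,
   "phi_printed": "1"
  },
  {
   "label": "Y",
   "codons": [
    "TTG"
   ],
   "psi": 0.996719,
   "phi_printed": "1"
  },
  {
   "label": "*",
   "codons": [
    "TGG"
   ],
   "psi": 0.573441,
   "phi_printed": "1"
  }
 ]
}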