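{
 "scenario": "M3",
 "groups": [
  {
   "label": "A",
   "codons": [
    "AAG",
    "TAG",
    "TTC",
    "CAG"
   ],
   "psi": 0.7453878,
   "phi_printed": "5/6"
  },
  {
   "label": "C",
   "codons": [
    "ATC",
    "TTA",
    "GAA",
    "GTA"
   ],
   "psi": 0.734763,
   "phi_printed": "8/9"
  },
  {
   "label": "D",
   "codons": [
    "ACG",
    "CCA",
    "CCT",
    "CCG"
   ],
   "psi": 0.5928058,
   "phi_printed": "7/9"
  },
  {
   "label": "E",
   "codons": [
    "AGC",
    "CAC",
    "CGC",
    "CCC"
   ],
   "psi": 0.6837612,
   "phi_printed": "7/9"
  },
  {
   "label": "F",
   "codons": [
    "GAG",
    "GTG",
    "GCA",
    "GCG"
   ],
   "psi": 0.573447,
   "phi_printed": "7/9"
  },
  {
   "label": "G",
   "codons": [
    "ACT",
    "TCT",
    "GCT"
   ],
   "psi": 0.916417,
   "phi_printed": "7/9"
  },
  {
   "label": "H",
   "codons": [
    "AGG",
    "TGG",
    "CGG"
   ],
   "psi": 0.862386,
   "phi_printed": "7/9"
  },
  {
   "label": "I",
   "codons": [
    "TGC",
    "GTC",
    "GGC"
   ],
   "psi": 0.8267687,
   "phi_printed": "23/27"
  },
  {
   "label": "K",
   "codons": [
    "AGT",
    "TGT",
    "CGT"
   ],
   "psi": 0.8261313,
   "phi_printed": "7/9"
  },
  {
   "label": "L",
   "codons": [
    "ACC",
    "TCC",
    "GAC"
   ],
   "psi": 0.815771,
   "phi_printed": "25/27"
  },
  {
   "label": "M",
   "codons": [
    "ATG",
    "TTG",
    "CTG"
   ],
   "psi": 0.796867,
   "phi_printed": "7/9"
  },
  {
   "label": "N",
   "codons": [
    "GAT",
    "GGA",
    "GGT"
   ],
   "psi": 0.7812357,
   "phi_printed": "23/27"
  },
  {
   "label": "P",
   "codons": [
    "ATT",
    "GTT",
    "CAT"
   ],
   "psi": 0.774143,
   "phi_printed": "25/27"
  },
  {
   "label": "Q",
   "codons": [
    "TTT",
    "CTT",
    "CTC"
   ],
   "psi": 0.7475287,
   "phi_printed": "23/27"
  },
  {
   "label": "R",
   "codons": [
    "AGA",
    "TGA",
    "CGA"
   ],
   "psi": 0.734763,
   "phi_printed": "7/9"
  },
  {
   "label": "S",
   "codons": [
    "ATA",
    "CAA",
    "CTA"
   ],
   "psi": 0.711267,
   "phi_printed": "23/27"
  },
  {
   "label": "T",
   "codons": [
    "TCG",
    "GGG",
    "GCC"
   ],
   "psi": 0.7241587,
   "phi_printed": "1"
  },
  {
   "label": "V",
   "codons": [
    "AAC",
    "TAC"
   ],
   "psi": 1.0,
   "phi_printed": "8/9"
  },
  {
   "label": "W",
   "codons": [
    "AAT",
    "TAT"
   ],
   "psi": 1.0,
   "phi_printed": "8/9"
  },
  {
   "label": "Y",
   "codons": [
    "ACA",
    "TCA"
   ],
   "psi": 1.0,
   "phi_printed": "8/9"
  },
  {
   "label": "*",
   "codons": [
    "AAA",
    "TAA"
   ],
   "psi": 1.0,
   "phi_printed": "8/9"
  }
 ]
}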