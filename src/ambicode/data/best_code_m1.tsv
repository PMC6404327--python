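codon	label
AAA	A
AAC	A
AAG	A
AAT	A
ACA	D
ACC	D
ACG	D
ACT	D
AGA	G
AGC	G
AGG	G
AGT	G
ATA	I
ATC	I
ATG	I
ATT	I
CAA	F
CAC	F
CAG	F
CAT	F
CCA	H
CCC	H
CCG	H
CCT	H
CGA	C
CGC	C
CGG	C
CGT	C
CTA	K
CTC	K
CTG	K
CTT	K
GAA	W
GAC	V
GAG	W
GAT	V
GCA	M
GCC	M
GCG	M
GCT	M
GGA	*
GGC	Y
GGG	Y
GGT	*
GTA	E
GTC	E
GTG	E
GTT	E
TAA	L
TAC	L
TAG	L
TAT	L
TCA	P
TCC	N
TCG	N
TCT	P
TGA	T
TGC	S
TGG	T
TGT	S
TTA	Q
TTC	R
TTG	Q
TTT	R
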