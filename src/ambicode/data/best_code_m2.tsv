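codon	label
AAA	M
AAC	M
AAG	L
AAT	L
ACA	K
ACC	H
ACG	R
ACT	I
AGA	K
AGC	H
AGG	L
AGT	I
ATA	K
ATC	H
ATG	R
ATT	I
CAA	C
CAC	A
CAG	A
CAT	A
CCA	C
CCC	P
CCG	A
CCT	H
CGA	C
CGC	M
CGG	A
CGT	Q
CTA	C
CTC	C
CTG	A
CTT	C
GAA	E
GAC	D
GAG	D
GAT	F
GCA	E
GCC	D
GCG	G
GCT	F
GGA	E
GGC	D
GGG	E
GGT	G
GTA	G
GTC	G
GTG	F
GTT	F
TAA	N
TAC	N
TAG	S
TAT	S
TCA	Q
TCC	V
TCG	P
TCT	P
TGA	W
TGC	V
TGG	*
TGT	T
TTA	Q
TTC	N
TTG	Y
TTT	T
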