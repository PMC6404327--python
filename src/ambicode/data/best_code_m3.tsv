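codon	label
AAA	*
AAC	V
AAG	A
AAT	W
ACA	Y
ACC	L
ACG	D
ACT	G
AGA	R
AGC	E
AGG	H
AGT	K
ATA	S
ATC	C
ATG	M
ATT	P
CAA	S
CAC	E
CAG	A
CAT	P
CCA	D
CCC	E
CCG	D
CCT	D
CGA	R
CGC	E
CGG	H
CGT	K
CTA	S
CTC	Q
CTG	M
CTT	Q
GAA	C
GAC	L
GAG	F
GAT	N
GCA	F
GCC	T
GCG	F
GCT	G
GGA	N
GGC	I
GGG	T
GGT	N
GTA	C
GTC	I
GTG	F
GTT	P
TAA	*
TAC	V
TAG	A
TAT	W
TCA	Y
TCC	L
TCG	T
TCT	G
TGA	R
TGC	I
TGG	H
TGT	K
TTA	C
TTC	A
TTG	M
TTT	Q
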