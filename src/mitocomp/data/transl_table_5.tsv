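codon	aa
TTT	F
TTC	F
TTA	L
TTG	L
TCT	S
TCC	S
TCA	S
TCG	S
TAT	Y
TAC	Y
TAA	*
TAG	*
TGT	C
TGC	C
TGA	W
TGG	W
CTT	L
CTC	L
CTA	L
CTG	L
CCT	P
CCC	P
CCA	P
CCG	P
CAT	H
CAC	H
CAA	Q
CAG	Q
CGT	R
CGC	R
CGA	R
CGG	R
ATT	I
ATC	I
ATA	M
ATG	M
ACT	T
ACC	T
ACA	T
ACG	T
AAT	N
AAC	N
AAA	K
AAG	K
AGT	S
AGC	S
AGA	S
AGG	S
GTT	V
GTC	V
GTA	V
GTG	V
GCT	A
GCC	A
GCA	A
GCG	A
GAT	D
GAC	D
GAA	E
GAG	E
GGT	G
GGC	G
GGA	G
GGG	G
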