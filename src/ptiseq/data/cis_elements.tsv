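name	family	consensus
GCC-box	AP2/ERF	AGCCGCC
DRE/CRT	AP2/ERF	(A/G)CCGAC
DRE-like	AP2/ERF	(A/G/T)(A/G)CCGACN(A/T)
Myc-related	MYC/NAC	CACATG
G-box	bZIP	CACGTG
G-box-like	bZIP	CACGT(A/T)
ABRE-like	bZIP	(C/G/T)ACGTG(G/T)(A/C)
ACTCAT-element	bZIP	ACTCAT
TGA-element	bZIP	TGACG
AtMyb1	MYB	(A/C)TCC(A/T)ACC
AtMyb2	MYB	(A/C)TCC(A/T)ACC
AtMyb3	MYB	TAACTAAC
AtMyb4	MYB	A(A/C)C(A/T)A(A/C)C
W-box	WRKY	TTGAC(C/T)
CG-1	CAMTA	(A/C/G)CGCG(T/C/G)
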