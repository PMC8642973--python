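approved_symbol	alias	cytoband
ABL1	ABL1	9q34.12
AGK	AGK	7q34
ALK	ALK	2p23.2
BCAN	BCAN	1q23.1
BCR	BCR	22q11.23
BRAF	BRAF	7q34
CCDC6	CCDC6	10q21.2
CD74	CD74	5q33.1
COL3A1	COL3A1	2q32.2
EML4	EML4	2p21
ETV6	ETV6	12p13.2
EWSR1	EWSR1	22q12.2
FGFR1	FGFR1	8p11.23
FGFR3	FGFR3	4p16.3
FLI1	FLI1	11q24.3
FOXO1	FOXO1	13q14.11
GOPC	GOPC	6q22.1
HMGA2	HMGA2	12q14.3
KIAA1549	KIAA1549	7q34
KIF5B	KIF5B	10p11.22
KMT2A	KMT2A	11q23.3
LMNA	LMNA	1q22
MET	MET	7q31.2
NCOA4	NCOA4	10q11.22
NPM1	NPM1	5q35.1
NTRK1	NTRK1	1q23.1
NTRK3	NTRK3	15q25.3
PAX3	PAX3	2q36.1
PAX8	PAX8	2q14.1
PBX1	PBX1	1q23.3
PLAG1	PLAG1	8q12.1
PPARG	PPARG	3p25.2
RBPMS	RBPMS	8p12
RELA	RELA	11q13.1
RET	RET	10q11.21
ROS1	ROS1	6q22.1
RUNX1	RUNX1	21q22.12
SLC34A2	SLC34A2	4p15.2
SND1	SND1	7q32.1
TACC1	TACC1	8p11.23
TACC3	TACC3	4p16.3
TCF3	TCF3	19p13.3
TFG	TFG	3q12.2
TPM3	TPM3	1q21.3
TRIM22	TRIM22	11p15.4
ZFTA	ZFTA	11q13.1
ABL1	ABL	9q34.12
CCDC6	D10S170	10q21.2
EWSR1	EWS	22q12.2
FOXO1	FKHR	13q14.11
KMT2A	MLL	11q23.3
NPM1	B23	5q35.1
NTRK1	TRKA	1q23.1
NTRK3	TRKC	15q25.3
RUNX1	AML1	21q22.12
TCF3	E2A	19p13.3
ZFTA	C11orf95	11q13.1
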