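# Seed list of known pathogenic fusion gene pairs (unordered).
# Users should supply their own curated list for production use.
EWSR1	FLI1
KIAA1549	BRAF
SND1	BRAF
AGK	BRAF
BCR	ABL1
ETV6	NTRK3
ETV6	RUNX1
NPM1	ALK
EML4	ALK
ZFTA	RELA
PAX3	FOXO1
FGFR1	TACC1
FGFR3	TACC3
KIF5B	RET
CCDC6	RET
NCOA4	RET
TPM3	NTRK1
LMNA	NTRK1
BCAN	NTRK1
SLC34A2	ROS1
CD74	ROS1
GOPC	ROS1
COL3A1	PLAG1
TCF3	PBX1
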