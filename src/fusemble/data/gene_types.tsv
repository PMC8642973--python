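gene	gene_type
ABL1	non-receptor tyrosine kinase
AGK	acylglycerol kinase
ALK	receptor tyrosine kinase
BCAN	extracellular matrix proteoglycan
BCR	GTPase-activating protein
BRAF	serine/threonine-protein kinase
CCDC6	coiled-coil domain protein
CD74	MHC class II chaperone
COL3A1	fibrillar collagen
EML4	microtubule-associated protein
ETV6	ETS-family transcription factor
EWSR1	RNA-binding protein
FGFR1	receptor tyrosine kinase
FGFR3	receptor tyrosine kinase
FLI1	ETS-family transcription factor
FOXO1	forkhead transcription factor
GOPC	Golgi-associated PDZ protein
KIAA1549	UPF0606 membrane protein
KIF5B	kinesin motor protein
KMT2A	histone lysine methyltransferase
LMNA	nuclear lamin
MET	receptor tyrosine kinase
NCOA4	nuclear receptor coactivator
NPM1	nucleolar phosphoprotein
NTRK1	receptor tyrosine kinase
NTRK3	receptor tyrosine kinase
PAX3	paired-box transcription factor
PBX1	homeobox transcription factor
PLAG1	zinc finger transcription factor
RBPMS	RNA-binding protein
RELA	NF-kB subunit transcription factor
RET	receptor tyrosine kinase
ROS1	receptor tyrosine kinase
RUNX1	runt-domain transcription factor
SLC34A2	sodium-phosphate transporter
SND1	transcriptional coactivator nuclease
TACC1	coiled-coil centrosomal protein
TACC3	coiled-coil centrosomal protein
TCF3	bHLH transcription factor
TFG	TRK-fused gene protein
TPM3	tropomyosin
TRIM22	E3 ubiquitin ligase
ZFTA	zinc finger translocation-associated protein
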