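symbol	chrom	strand	band	start	end
ABL1	9	+	9q34.12	130713881	130887675
AGK	7	+	7q34	141551282	141662176
ALK	2	-	2p23.2	29192774	29921586
BCAN	1	+	1q23.1	156641424	156659114
BCR	22	+	22q11.23	23180365	23318037
BRAF	7	-	7q34	140719327	140924929
CCDC6	10	-	10q21.2	59786748	59906937
CD74	5	-	5q33.1	150401637	150412929
COL3A1	2	+	2q32.2	188974373	189012746
EML4	2	+	2p21	42169353	42332548
ETV6	12	+	12p13.2	11802788	12048336
EWSR1	22	+	22q12.2	29268009	29300525
FGFR1	8	-	8p11.23	38411138	38468834
FGFR3	4	+	4p16.3	1793293	1808872
FLI1	11	+	11q24.3	128556430	128683162
FOXO1	13	-	13q14.11	40555667	40666641
GOPC	6	-	6q22.1	117223141	117266690
HMGA2	12	+	12q14.3	65824460	65966291
KIAA1549	7	-	7q34	138831377	139002729
KIF5B	10	-	10p11.22	32009426	32056286
KMT2A	11	+	11q23.3	118436492	118526832
LMNA	1	+	1q22	156082573	156140081
MET	7	+	7q31.2	116672196	116798377
NCOA4	10	-	10q11.22	46001200	46027733
NPM1	5	+	5q35.1	171387116	171410900
NTRK1	1	+	1q23.1	156815750	156881850
NTRK3	15	-	15q25.3	87859751	88256768
PAX3	2	-	2q36.1	222199887	222298996
PAX8	2	-	2q14.1	113215997	113278921
PBX1	1	+	1q23.3	164528596	164821060
PLAG1	8	-	8q12.1	56160909	56211273
PPARG	3	+	3p25.2	12287368	12434356
RBPMS	8	+	8p12	30384513	30572642
RELA	11	-	11q13.1	65653596	65663090
RET	10	+	10q11.21	43077069	43130351
ROS1	6	-	6q22.1	117287825	117425855
RUNX1	21	-	21q22.12	34787801	35049344
SLC34A2	4	+	4p15.2	25655477	25680370
SND1	7	+	7q32.1	127632066	128069995
TACC1	8	+	8p11.23	38644722	38710546
TACC3	4	+	4p16.3	1721490	1745176
TCF3	19	-	19p13.3	1609289	1652615
TFG	3	+	3q12.2	100709802	100748950
TPM3	1	-	1q21.3	154155308	154194648
TRIM22	11	+	11p15.4	5690250	5710655
ZFTA	11	-	11q13.1	65916280	65933865
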