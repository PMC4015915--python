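taxon	DENV3	JEV	BVDV1	HCV1	PolV1	HuRV16	HuRV1B	CoxVB3	FMDV	NORV	MuNORV1	RHEV	SappV	Phi6	Qbeta	IBDV	IPNV	SRV	MORV3	HIV1	HIV2
JEV	42,9	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
BVDV1	22,8	21,7	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
HCV1	20,5	17,4	27,4	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
PolV1	18,1	16,8	25,3	21,5	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
HuRV16	18,2	16,6	25,1	20,9	52,4	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
HuRV1B	18,0	16,5	24,8	20,7	52,2	56,7	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
CoxVB3	18,0	16,3	25,2	21,0	53,1	52,4	53,1	-	-	-	-	-	-	-	-	-	-	-	-	-	-
FMDV	19,2	17,2	26,5	21,6	41,5	41,3	41,0	41,6	-	-	-	-	-	-	-	-	-	-	-	-	-
NORV	20,5	17,5	27,1	23,8	32,0	32,3	38,1	31,8	32,4	-	-	-	-	-	-	-	-	-	-	-	-
MuNORV1	20,9	17,7	28,0	25,2	31,1	31,5	31,2	31,4	32,2	51,0	-	-	-	-	-	-	-	-	-	-	-
RHEV	18,7	17,9	27,4	24,3	32,4	33,0	32,9	33,0	32,4	39,3	42,7	-	-	-	-	-	-	-	-	-	-
SappV	17,5	15,0	24,7	20,6	30,4	30,8	30,8	30,9	30,8	39,1	39,4	43,9	-	-	-	-	-	-	-	-	-
Phi6	14,8	10,6	4,1	16,4	17,2	17,0	16,9	17,7	15,7	18,5	19,1	17,7	14,1	-	-	-	-	-	-	-	-
Qbeta	11,1	7,7	14,8	14,1	14,0	13,5	13,6	14,5	13,8	13,2	14,4	14,9	12,6	12,3	-	-	-	-	-	-	-
IBDV	8,4	6,6	10,7	9,5	12,1	12,1	11,9	12,6	12,9	13,4	13,3	12,6	12,9	9,5	6,0	-	-	-	-	-	-
IPNV	9,8	6,7	13,9	12,9	12,4	12,3	12,1	13,0	13,5	15,5	14,2	14,0	13,2	10,7	7,7	42,5	-	-	-	-	-
SRV	8,9	9,0	10,2	10,5	9,7	9,4	8,3	8,4	9,3	9,4	9,1	10,4	8,5	9,9	7,8	4,6	4,6	-	-	-	-
MORV3	6,5	4,0	10,3	7,6	7,8	7,3	7,1	7,8	8,1	7,9	7,9	8,1	8,0	8,4	8,0	6,5	6,6	15,4	-	-	-
HIV1	4,7	1,6	6,3	6,5	5,4	5,5	4,9	4,8	5,3	5,5	5,7	5,7	4,9	3,8	5,8	2,8	2,3	4,0	5,9	-	-
HIV2	5,4	4,0	7,9	7,4	6,2	6,6	6,8	6,9	6,1	7,6	7,9	6,5	7,4	5,5	7,7	3,6	4,3	4,6	5,1	28,5	-
MoMLV	4,7	3,4	7,9	6,2	7,2	7,4	7,0	6,8	6,0	7,6	6,8	7,5	7,4	4,9	6,2	2,6	3,0	4,0	3,9	18,2	20,7
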