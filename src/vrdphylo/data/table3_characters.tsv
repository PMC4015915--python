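taxon	A	B	C	D	E	F	G	H	I	J	K	L	M	N	O	P	Q	R	S	T	U
DENV3	0	0	0	0	0	0	N	1	0	0	0	0	2	0	0	0	0	0	0	0	1
JEV	0	0	0	0	0	0	0	1	0	0	0	0	2	0	0	0	0	0	0	0	1
BVDV1	0	0	0	0	0	0	0	1	1	0	0	0	1	1	0	0	0	0	0	0	1
HCV1	0	0	0	0	0	0	0	1	1	0	1	0	0	1	0	1	0	0	0	0	1
PolV1	0	0	1	0	0	0	0	1	2	0	0	0	1	1	0	2	0	0	0	1	0
HuRV16	0	0	1	0	0	0	0	1	2	0	0	0	1	1	0	2	0	0	0	1	0
HuRV1B	0	0	1	0	0	0	0	1	2	0	0	0	1	1	0	2	0	0	0	1	0
CoxVB3	0	0	1	0	0	0	0	1	1	0	0	0	1	1	0	2	0	0	0	1	0
FMDV	0	0	1	0	0	0	0	1	2	0	0	0	1	1	0	2	0	0	0	1	0
NORV	0	0	1	0	0	0	0	1	2	0	0	0	1	1	0	2	0	0	0	1	0
MuNORV1	0	0	1	0	0	0	0	1	2	0	0	0	1	1	0	1	0	0	0	1	0
RHEV	0	0	1	0	0	0	0	1	1	0	1	0	1	1	0	2	0	0	0	1	0
SappV	0	0	1	0	0	0	0	1	2	0	1	0	1	1	0	1	0	0	0	1	0
Phi6	0	0	0	0	0	2	1	1	1	0	0	0	2	1	0	2	1	0	1	1	2
Qbeta	0	0	0	1	0	1	1	1	2	0	0	0	1	0	0	1	0	0	1	1	0
IBDV	0	0	1	1	1	0	0	1	1	0	0	0	0	1	0	2	0	1	0	1	0
IPNV	0	0	1	1	1	0	0	1	1	0	0	0	0	1	0	2	0	1	0	1	0
SRV	0	0	0	0	0	1	2	1	1	0	0	0	0	1	1	2	0	0	1	1	3
MORV3	0	0	0	0	0	1	2	1	1	1	1	1	2	1	1	2	0	0	1	1	3
HIV1	1	1	2	1	0	1	2	0	2	2	0	1	0	1	0	1	0	0	1	1	0
HIV2	1	1	2	1	0	1	2	0	2	2	0	1	0	1	0	1	0	0	1	1	0
MoMLV	1	1	2	1	0	1	2	0	2	2	0	1	0	1	0	1	0	0	1	1	0
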