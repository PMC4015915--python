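baltimore_class	family	genus	virus	abbreviation	pdb_id	chain	resolution	cocrystallized	has_mutation	has_bound_template_or_substrate
IV	Caliciviridae	Lagovirus	Rabbit hemorrhagic disease virus	RHEV	1KHV	B	2,5	Lu2+	0	0
IV	Caliciviridae	Norovirus	Murine norovirus	MuNORV1	3UQS	A	2	SO4^2-	0	0
IV	Caliciviridae	Norovirus	Norovirus	NORV	3BSO	A	1,74	Mg2+;CTP;RNA	0	1
IV	Caliciviridae	Sapovirus	Sapporo virus	SappV	2CKW	A	2,3		0	0
IV	Flaviviridae	Flavivirus	Dengue virus 3	DENV3	2J7W	A	2,6	Zn2+;GTP	0	1
IV	Flaviviridae	Flavivirus	Japanese encephalitis virus	JEV	4K6M	A	2,6	SAH;SO4^2-;Zn2+	0	0
IV	Flaviviridae	Hepacivirus	Hepatitis C virus 1	HCV1	1NB6	A	2,6	Mn2+;UTP	0	1
IV	Flaviviridae	Pestivirus	Bovine viral diarrhea virus	BVDV1	1S49	A	3	GTP	0	1
IV	Leviviridae	Allolevivirus	Enterobacterio phage Qbeta	Qbeta	3AVX	A	2,41	Ca2+;3'dGTP;RNA	0	1
IV	Picornaviridae	Aphthovirus	Foot and mouth disease virus	FMDV	2E9Z	A	3	Mg2+;UTP;PPi;RNA	0	1
IV	Picornaviridae	Enterovirus	Humane rhinovirus 16 A	HuRV16	1XR7	A	2,3		0	0
IV	Picornaviridae	Enterovirus	Coxsackie virus B3	CoxVB3	3CDW	A	2,5	PPi	0	0
IV	Picornaviridae	Enterovirus	Humane rhinovirus 1B	HuRV1B	1XR6	A	2,5	K+	0	0
IV	Picornaviridae	Enterovirus	Poliovirus 1	PolV1	3OLB	A	2,41	Zn2+;ddCTP;RNA	0	1
III	Birnaviridae	Aquabirnavirus	Infectious pancreatic necrosis virus	IPNV	2YI9	A	2,2	Mg2+	0	0
III	Birnaviridae	Avibirnavirus	Infectious bursal disease virus	IBDV	2PUS	A	2,4		0	0
III	Cystoviridae	Cystovirus	Pseudomonas phage phi6	Phi6	1HI0	P	3	Mn2+;Mg2+;GTP;DNA	0	1
III	Reoviridae	Orthoreovirus	Mammalian orthoreovirus 3	MORV3	1N35	A	2,5	Mn2+;3'dCTP;RNA	0	1
III	Reoviridae	Rotavirus	Simian rotavirus Sa11	SRV	2R7W	A	2,6	GTP;RNA	0	1
VI	Retroviridae	Gammaretrovirus	Moloney murine leukemia virus	MoMLV	1RW3	A	3		0	0
VI	Retroviridae	Lentivirus	Human immunodeficiency virus 2	HIV2	1MU2	A	2,35	SO4^2-	0	0
VI	Retroviridae	Lentivirus	Human immunodeficiency virus 1	HIV1	3V81	C	2,85	nepavirine;DNA	0	1
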