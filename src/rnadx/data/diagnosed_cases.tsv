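case_index	patient_id	diagnosed_gene	variant_classes	rna_defects	status
1	R62943	C19orf70	frameshift;intronic	AE,AS	diagnosed
2	R98254	MRPL38	missense;UTR	AE	diagnosed
3	R86287	DARS2	splice donor;MNV	AS	diagnosed
4	R89912	NFU1	missense;deletion	AE,MAE	diagnosed
5	R19100	SLC25A4	splice region	AE	diagnosed
6	R15264	TIMMDC1	intronic	AE,AS,Var	diagnosed
7	R36605	TWNK	synonymous	AE,AS	diagnosed
8	R61100	NAXE	intronic	AE,AS	diagnosed
9	R77611	DLD	missense	AE,MAE	diagnosed
10	R16472	MRPS25	intronic	AE,AS,Var	diagnosed
11	R51757	NDUFA10	UTR	AE	diagnosed
12	R80346	LIG3	stop;intronic	AE,Var	diagnosed
13	R20754	UFM1	promoter	AE	diagnosed
14	R25473	PEX1	frameshift;intronic	AE,Var	diagnosed
15	R28774	TIMMDC1	intronic	AE,AS,Var	diagnosed
16	R96820	CLPP	splice region	AE,AS	diagnosed
17	R21147	NDUFA10	UTR	AE	diagnosed
18	R64921	MCOLN1	intronic;stop	AE,AS	diagnosed
19	R52016	TIMMDC1	intronic	AE,AS,Var	diagnosed
20	R46723	NDUFAF5	start loss;intronic	AE,AS,Var	diagnosed
21	R58859	TAZ	synonymous	AS	diagnosed
22	R80184	ALDH18A1	stop;missense	AE,MAE	diagnosed
23	R59185	NDUFS4	frameshift	AE	diagnosed
24	R63087	SLC25A42	splice donor	AS	diagnosed
25	R44456	MRPL44	splice region	AE,AS	diagnosed
26	R33391	NDUFAF5	frameshift;intronic	AS,Var	diagnosed
27	R66696	LPIN1	deletion	AS	diagnosed
28	R24289	RRM2B	missense;intergenic	AE,MAE	diagnosed
29	R98349	DLD	missense;splice region	AS	diagnosed
30	R91273	ETFDH	frameshift	AE	diagnosed
31	R60537	ATP6AP1	intronic	AE,Var	diagnosed
32	R70961	PTCD3	splice acceptor;missense	AS	diagnosed
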