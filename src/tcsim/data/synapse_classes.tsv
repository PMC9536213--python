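index	bbp_id	s_type	p_type	gsyn_mean	gsyn_sd	tau_decay_mean	tau_decay_sd	U_mean	U_sd	D_mean	D_sd	F_mean	F_sd	rule
0	0	I1	II	0.83	0.55	10.40	6.10	0.16	0.100	45	21	376	253	L6:L6_(DBC-LBC-NBC-SBC)
1	3	I1	IE	0.91	0.61	10.40	6.10	0.16	0.100	45	21	376	253	SBC_cAC:Exc or L6_(NBC-LBC):L6_BPC
2	13	I1	IE	0.75	0.32	10.40	6.10	0.41	0.212	162	69	690	5	L6_MC:L6_IPC
3	1	I2	II	0.83	0.55	8.30	2.20	0.25	0.130	706	405	21	9	L1:Excitatory or Inhibitory:Inhibitory
4	4	I2	IE	0.91	0.61	8.30	2.20	0.25	0.130	706	405	21	9	SBC_dNAC:Excitatory
5	8	I2	IE	0.75	0.32	8.30	2.20	0.25	0.130	706	405	21	9	BTC-DBC-BP:Excitatory
6	9	I2	IE	0.75	0.32	8.30	2.20	0.30	0.080	1250	520	2	4	MC:Excitatory
7	10	I2	IE	0.91	0.61	8.30	2.20	0.14	0.050	875	285	22	5	LBC-NBC_(bAC cAC bNAC dNAC):Excitatory
8	12	I2	IE	2.97	0.95	8.30	2.20	0.25	0.130	706	405	21	9	Chc:Excitatory
9	5	I3	IE	0.91	0.61	6.44	1.70	0.32	0.140	144	80	62	31	SBC_bNAC or LBC-NBC_(cNAC dSTUT cSTUT bSTUT):Excitatory
10	11	I3	IE	0.83	0.55	36.55	0.71	0.25	0.130	706	405	21	9	NGC:Excitatory
11	114	E1	EI	0.43	0.28	1.74	0.18	0.02	0.001	194	10	507	20	Exc:(BP_cAC DBC_cAC BTC_cAC)
12	115	E1	EI	0.72	0.50	1.74	0.18	0.02	0.001	194	10	507	20	Exc:(NBC-LBC)_(cAC cIR bAC bIR cNAC)
13	132	E1	EI	0.72	0.50	1.74	0.18	0.01	0.001	242	15	563	32	L6_TPC_L:L6_(DBC-LBC-NBC-SBC)
14	133	E1	EI	0.11	0.08	1.74	0.18	0.09	0.120	138	211	670	830	Excitatory:MC
15	116	E2	EE	0.72	0.50	1.74	0.18	0.50	0.020	671	17	17	5	Excitatory:Excitatory
16	117	E2	EI	0.43	0.28	1.74	0.18	0.50	0.020	671	17	17	5	Excitatory:[L1-BP_(cNAC bNAC)-DBC_bAC-BTC_(bAC cNAC bIR)]
17	118	E2	EI	0.72	0.50	1.74	0.18	0.50	0.020	671	17	17	5	Excitatory:SBC-ChC
18	119	E2	EE	0.68	0.46	1.74	0.18	0.46	0.260	671	17	17	5	L23_PC:L23_PC
19	120	E2	EE	0.68	0.46	1.74	0.18	0.86	0.049	671	17	17	5	L4_Excitatory:L4_Excitatory
20	121	E2	EE	0.19	0.12	1.74	0.18	0.79	0.040	671	17	17	5	L4_SS:L23_PC
21	122	E2	EE	0.80	0.53	1.74	0.18	0.39	0.030	671	17	17	5	L5_STPC:L5_STPC
22	123	E2	EE	1.50	1.05	1.74	0.18	0.50	0.020	671	17	17	5	L5_TTPC:L5_TTPC
23	127	E2	EE	0.80	0.53	1.74	0.18	0.39	0.134	780	54	51	36	L6_IPC:L6_IPC
24	131	E2	EI	0.72	0.50	1.74	0.18	0.58	0.070	240	43	71	47	L6_IPC:L6_(DBC-LBC-NBC-SBC)
25	134	E2	EI	0.72	0.50	1.74	0.18	0.72	0.065	227	38	14	12	Exc:(NBC-LBC)_(bSTUT dNAC bNAC cSTUT)
26	126	E3	EE	0.80	0.53	1.74	0.18	0.21	0.032	460	53	230	69	L6_TPC_L:L6_TPC_L
27	128	E3	EE	0.80	0.53	1.74	0.18	0.27	0.033	559	238	200	92	L6_IPC:L6_BPC
28	129	E3	EE	0.80	0.53	1.74	0.18	0.22	0.053	535	134	116	81	L6_IPC:L6_TPC_L
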