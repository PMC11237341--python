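species	total_length	pctT	pctC	pctA	pctG	pctAT	at_skew	gc_skew	accession
Boulenophrys sangzhiensis	16950	30.77	26.97	27.45	14.81	58.21	-0.057	-0.291	OQ830572
Boulenophrys tuberogranulata	16841	30.91	26.75	27.79	14.55	58.70	-0.053	-0.295	OQ830573
Boulenophrys jingganggensis	17262	31.62	26.28	27.62	14.48	59.24	-0.067	-0.289	MT683772
Boulenophrys omeimontis	17013	31.76	25.72	28.34	14.18	60.10	-0.057	-0.289	KP728257
Boulenophrys spinata	16024	30.63	27.11	27.16	15.10	57.79	-0.060	-0.284	ON646614
Boulenophrys boettgeri	16597	31.51	26.42	27.84	14.23	59.35	-0.062	-0.300	OR529440
Boulenophrys kuatunensis	17921	32.07	25.86	28.10	13.97	60.17	-0.066	-0.298	OR522721
Boulenophrys baishanzuensis	17040	31.51	26.64	27.24	14.61	58.75	-0.073	-0.292	OR063945
Brachytarsophrys carinense	15271	29.80	27.61	27.46	15.13	57.26	-0.041	-0.292	JX564854
Leptobrachium boringii	17097	31.53	25.51	27.69	15.27	59.22	-0.065	-0.251	OP373724
Leptobrachium liui	17499	32.74	24.32	28.10	14.84	60.84	-0.076	-0.242	OP503540
Oreolalax major	17786	32.63	24.31	28.75	14.31	61.37	-0.063	-0.259	MN803320
Oreolalax xiangchengensis	17110	33.02	23.62	29.18	14.18	62.20	-0.062	-0.250	MH727696
Oreolalax jingdongensis	17864	32.73	23.92	29.10	14.26	61.82	-0.059	-0.253	MF953479
Oreolalax omeimontis	17675	32.59	24.96	28.46	13.99	61.05	-0.068	-0.282	MN803321
Oreolalax multipunctatus	17358	32.96	24.20	28.53	14.31	61.49	-0.072	-0.257	MF966382
Oreolalax lichuanensis	17702	32.17	24.86	28.00	14.98	60.17	-0.069	-0.248	KU096847
Oreolalax schmidti	18481	32.80	24.48	28.31	14.41	61.11	-0.073	-0.259	MT773151
Oreolalax rhodostigmatus	18676	32.39	24.93	28.03	14.66	60.42	-0.072	-0.259	MF770485
Leptobrachium ailaonicum	17318	31.83	24.99	27.90	15.27	59.74	-0.066	-0.241	MZ394043
Leptobrachium leishanense	17485	32.64	24.38	28.15	14.83	60.79	-0.074	-0.244	KU760082
Scutiger ningshanensis	17265	32.68	24.25	29.11	13.96	61.79	-0.058	-0.269	KX619450
Scutiger liupanensis	16888	32.25	24.90	28.32	14.53	60.57	-0.065	-0.263	KX352261
Leptolalax oshanensis	17747	29.85	26.26	28.77	15.11	58.62	-0.018	-0.270	KC460337
Leptobrachella alpina	17763	30.77	25.64	28.53	15.05	59.30	-0.038	-0.260	MW487804
Leptolalax pelodytoides	14682	29.07	27.80	27.67	15.46	56.74	-0.025	-0.285	JX564874
Atympanophrys shapingensis	17631	31.48	26.05	28.18	14.29	59.66	-0.055	-0.291	JX458090
Atympanophrys gigantica	18259	32.11	25.19	28.37	14.33	60.48	-0.062	-0.275	MZ364157
Microhyla fissipes	16723	31.01	25.48	28.93	14.58	59.94	-0.035	-0.272	MN046210
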