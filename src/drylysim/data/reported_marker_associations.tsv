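snp	trait	support	linkage_group	position_cm	african_cowpea_trait	qtl
1_1258	Stg	G2011, M2011, 2012	LG2	16.45
1_1181	Scu	G2012, 2014, M2014	LG2	35.49
1_0693	Scu	G2011, 2014, M2014	LG2	35.76
1_1140	Scu	G2012, 2014, M2014	LG2	35.76
1_1352	Scu	M2011, 2014	LG2	57.49	Senescence	Dro-9
1_1021	Scu	G2011, 2014	LG2	71.25		Dro-9
1_1021	Stg	G2011, 2014, M2011	LG2	71.25
1_1481	Stg	G2011, M2011, 2014	LG2	71.66
1_0724	Scu	G2011, 2012, M2011	LG3	11.96
1_1483	Stg	G2011, 2014	LG3	33.34
1_0636	Scu	G2011, 2012	LG3	38.59	Biomass
1_1349	Scu	G2011, 2012	LG3	39.83	Senescence
1_0758	Scu	G2011, 2012	LG3	44.93
1_1022	Scu	G2011, 2012	LG3	44.93
1_1427	Scu	G2011, 2012	LG3	44.93
1_0086	Scu	G2011, 2012	LG3	45.02
1_0064	Scu	G2011, 2012	LG3	45.73
1_1005	Wt	G2011, 2014	LG3	52.26
1_0380	Stg	G2011, M2011, 2014	LG3	73.42
1_1162	Stg	G2011, M2011	LG3	73.79
1_0888	Scu	G2011, 2012, 2014, M2012, 2014	LG4	0.72	Seed weight per plant
1_1147	Scu	G2011, 2012, 2014, M2011	LG4	2.77	Grain yield
1_0128	Stg	G2011, 2014	LG4	29.51
1_0205	Scu	G2011, 2012, M2012	LG5	43.29
1_0127	Stg	G2011, 2014	LG5	44.42	Seed weight per plant
1_0032	Scu	G2011, 2012, M2012	LG5	45.27
1_0664	Scu	G2011, 2012	LG6	59.00
1_1057	Wt	G2011, M2012	LG7	27.33	100-seed weight	Dro1
1_1057	Stg	G2011, M2011, 2012	LG7	27.33		Dro1
1_0298	Scu	G2012, M2012, 2014	LG8	3.80
1_0771	Scu	G2011, 2012	LG8	10.64
1_0838	Wt	G2011, 2014	LG8	42.11	Seed number per plant	Dro-3
1_1374	Scu	G2011, 2012	LG8	45.26		Dro-3
1_1167	Scu	M2011, 2014	LG9	0.20
1_0097	Scu	M2011, 2014	LG9	8.60	Grain yield
1_0474	Scu	M2011, 2014	LG9	40.27
1_0759	Stg	G2011, M2011, 2014	LG10	40.74	Seed number per pod	Dro-3
1_0603	Scu	G2011, 2012, M2012	LG11	4.60		Dro-3
1_0905	Scu	G2011, 2012	LG11	5.71		Dro-3
1_0486	Wt	G2012, M2014	LG11	23.14		Dro-3
1_0274	Stg	G2012, M2014	LG11	26.78		Dro-3
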