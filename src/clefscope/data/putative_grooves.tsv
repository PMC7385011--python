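seq_id	organism	r_GH9	h_GH9	l_GH9	r_CBM49	h_CBM49	l_CBM49
orange1.1g043219m	Citrus sinensis	13.60	3.50	170.78	11.29	4.40	141.76
ppa022524m	Prunus persica	11.65	3.71	146.38	13.29	4.06	166.87
SapurV1A.0237s0330.1.p	Salix purpurea	13.68	3.74	171.84	6.09	3.73	76.50
Carubv10003874m	Capsella rubella	13.50	3.28	169.59	10.11	3.90	126.99
Pavir.Eb00189.1.p	Panicum virgatum	13.55	3.53	170.15	8.76	4.06	110.04
Bradi5g026010.1.p	Bradipodium distachyon	9.79	3.64	123.02	14.46	4.08	181.58
Brara.E01714.1.p	Brassica rapa	8.06	4.00	101.18	10.23	4.28	128.52
Pavir.Ea00142.1.p	Panicum virgatum	12.12	3.66	152.23	6.31	2.70	79.25
GRMZM2G143747_P01	Zea mays	15.45	3.32	194.11	9.71	4.61	121.95
SapurV1A.0035s0560.1.p	Salix purpurea	14.64	3.47	183.88	8.48	3.78	106.56
Bradi2g07150.1.p	Bradipodium distachyon	13.45	3.94	168.96
PGSC0003DMP400021750	Solanum tuberosum	14.02	3.50	176.10	9.77	2.94	122.77
Migut.D01909.1.p	Mimulus guttatus	10.15	3.26	127.54	11.60	4.19	145.69
234652	Selaginella moellendorffii	9.30	4.07	116.79	10.93	4.09	137.30
MDP0000131267	Malus domestica	12.20	3.81	153.26	8.13	4.22	102.16
Potri.001G092200.1	Populus trichocarpa	12.44	3.79	156.30	9.47	3.20	118.92
GRMZM2G453565_P01	Zea mays	12.86	3.71	161.55	7.27	4.68	91.25
Solyc02g014220.2.1	Solanum lycopersicum	8.73	3.05	109.64	9.66	4.43	121.38
Aquca_037_00141.1	Aquilegia coerulea	12.83	3.96	161.16	6.80	2.67	85.35
Glyma.05G216400.1.p	Glycine max	13.34	3.68	167.55	5.91	3.24	74.26
489943	Arabidopsis lyrata	12.62	3.74	158.53	14.59	3.44	183.19
Bostr.25463s0223.1.p	Boechera stricta	13.46	3.67	169.11	12.65	3.65	158.85
Eucgr.J00862.1	Eucalyptus grandis	9.11	4.41	114.46	12.83	3.54	161.13
ppa002939m	Prunus persica	14.83	3.79	186.22	8.16	3.85	102.47
PGSC0003DMP400034548	Solanum tuberosum	8.54	3.40	107.32	8.66	3.21	108.72
Thhalv10028514m	Eutrema salsugineum	13.92	3.71	174.81	13.35	3.97	167.66
Medtr4g074960.1	Medicago truncatula	9.77	3.75	122.77	8.91	4.48	111.90
Gorai.005G210200.1	Gossypium raimondii	11.43	3.57	143.52	10.27	3.78	128.96
Potri.003G139600.1	Populus trichocarpa	13.60	3.89	170.81	7.71	3.66	96.86
Sobic.003G015700.1.p	Sorghum bicolor	13.31	3.57	167.13	10.85	3.60	136.29
Brara.I01325.1.p	Brassica rapa	13.90	3.84	174.63	6.05	3.10	75.93
Cucsa.107370.1	Cucumis sativus	14.22	4.11	178.58	12.41	4.04	155.86
99802	Selaginella moellendorffii	9.71	4.13	122.00	8.00	4.70	100.49
Brara.C02656.1.p	Brassica rapa	13.86	3.68	174.09	12.82	3.95	160.97
Lus10032377	Linum usitatissimum	12.70	3.99	159.48	7.76	3.98	97.44
Lus10003888	Linum usitatissimum	12.45	4.17	156.38	6.27	2.83	78.77
Medtr8g099410.1	Medicago truncatula	13.71	3.81	172.20	7.92	3.04	99.49
AT4G11050.1	Arabidopsis thaliana	13.53	3.84	169.89	12.86	4.03	161.55
Bradi2g32270.1.p	Bradipodium distachyon	14.21	3.61	178.47	5.64	2.68	70.88
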