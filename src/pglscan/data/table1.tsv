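strain	strain_type	source	max_rls	mean_rls	rls_se	doubling_glucose_mean	doubling_glucose_se	doubling_glycerol_mean	doubling_glycerol_se	mtdna_relative_coverage	cell_size
Y55	Lab	Grape	47	27	3.43	63.79	3.56	110.31	1.13	4.46	10
SK1	Lab	Soil	45	27	3.39	51.62	33.95	189.60	11.74	5.36	13
UWOPS87-2421	Wild	Plant	35	19	3.72	32.91	5.96	107.01	0.74	4.16	12
UWOPS05-227.2	Wild	Bee	37	23	3.39	56.03	8.23	116.59	4.93	4.41	11
UWOPS05-217.3	Wild	Plant	42	24	3.51	62.77	9.14	115.71	5.52	4.41	11
UWOPS83-787.3	Wild	Fruit	52	30	4.16	42.96	9.47	106.65	1.46	4.49	10
Y12	Fermentation	Palm wine	55	37	3.92	58.91	1.83	117.73	3.92	4.79	10
YPS606	Wild	Oak tree	44	38	1.76	35.43	7.22	98.50	1.29	3.85	10
YPS128	Wild	Oak tree	54	33	4.61	34.78	5.68	97.67	1.83	3.02	10
378604X	Clinical	Sputum	31	23	2.06	65.04	2.64	204.72	10.88	4.42	12
273614N	Clinical	Fecal	45	28	3.55	72.75	3.63	109.31	1.24	5.60	13
YS9	Baking	Unknown	37	21	2.90	63.08	4.15	131.35	0.91	3.29	14
BC187	Fermentation	Barrel	60	39	5.39	64.03	2.46	117.93	0.35	7.38	10
L-1374	Fermentation	Must	47	30	3.63	58.68	1.75	104.74	1.34	4.99	12
DBVPG6765	Unknown	Unknown	16	10	1.76	62.60	2.91	99.16	5.06	4.00	13
DBVPG1106	Fermentation	Grapes	32	24	2.00	64.70	2.26	109.41	1.52	5.46	12
YJM978	Clinical	Vaginal	18	9	1.76	64.20	1.89	110.30	4.21	5.75	12
YJM981	Clinical	Vaginal	50	25	4.78	67.68	1.43	102.18	3.16	7.98	14
YJM975	Clinical	Vaginal	52	34	5.18	63.07	2.89	106.81	3.28	5.95	11
DBVPG1373	Wild	Soil	35	23	3.02	66.58	4.93	123.39	2.48	4.87	11
NCYC361	Fermentation	Wort	7	3	0.53	62.97	2.84	117.85	0.75	5.19	12
YS2	Baking	Unknown	9	3	0.57	87.55	4.67	216.05	2.31	4.24	11
BY4743	Lab	Grape	44	28	1.67	76.38	2.89	163.62	7.17	4.46	NA
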