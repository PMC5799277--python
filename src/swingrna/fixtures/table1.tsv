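label	n	loop	eloop	stem_gc	loop_gc	cluster
Circ1	22	36.36	62.50	36.36	27.27	B1
Circ2	22	27.27	83.33	27.27	27.27	B1
Circ3	22	59.09	38.46	59.09	27.27	D2
Circ4	22	54.55	41.67	54.55	27.27	D2
Circ5	22	63.64	35.71	63.64	27.27	D2
Circ6	22	54.55	35.71	63.64	27.27	D2
Circ7	22	72.73	25.00	54.55	13.64	D2
Circ8	22	54.55	31.25	72.73	27.27	D1
Circ9	22	45.46	41.67	54.55	27.27	D2
Circ10	22	18.18	30.00	45.46	13.64	D2
Circ11	22	18.18	75.00	18.18	13.64	B1
Circ12	22	63.64	75.00	18.18	13.64	B1
Circ13	22	54.55	35.71	63.64	27.27	D2
Circ14	22	27.27	25.00	54.55	13.64	D2
Circ15	22	18.18	50.00	27.27	13.64	B1
Circ16	22	18.18	75.00	18.18	13.64	B1
Circ17	22	54.55	75.00	18.18	13.64	B1
Circ18	22	63.64	25.00	54.55	13.64	D2
Circ19	22	18.18	21.43	63.64	13.64	D1
Circ20	22	27.27	75.00	18.18	13.64	B1
Circ21	22	27.27	50.00	27.27	13.64	B1
Circ22	22	27.27	50.00	27.27	13.64	B1
Circ23	22	27.27	83.33	27.27	27.27	B1
Circ24	22	27.27	83.33	27.27	27.27	B1
De novo	51	16.67	40.00	56.00	60.00	B2
MITE16	48	70.83	23.53	78.57	38.24	D1
MITE20	66	48.48	28.13	58.82	28.13	D1
MITE4	27	85.19	17.39	50.00	43.48	D2
MITE21	60	85.00	54.90	90.00	35.29	D2
MITE14	60	66.67	32.50	70.00	32.50	D2
MITE8	57	68.42	53.85	100.00	30.77	D2
MITE2	43	67.44	17.24	64.29	34.48	D2
MITE25	62	54.84	38.24	64.29	20.59	D2
MITE9	66	54.55	36.11	80.77	27.78	D1
MITE7	57	68.42	30.77	50.00	33.33	D2
MITE12	68	64.71	22.73	87.50	31.82	D1
MITE29	62	70.97	34.09	94.44	27.27	D1
MITE28	71	61.97	20.45	84.62	31.82	D1
MITE24	64	59.38	23.68	50.00	28.95	D2
MITE19	67	71.64	22.92	80.00	35.42	D1
MITE17	65	73.85	29.17	87.50	37.50	D1
MITE10	72	52.78	47.37	82.35	36.84	D1
MITE26	62	67.74	26.19	70.00	26.19	D2
MITE13	63	68.25	76.74	95.00	27.91	D2
MITE22	62	64.52	32.50	75.00	35.00	D1
MITE5	45	60.00	37.04	68.75	33.33	D2
MITE11	41	56.10	26.09	88.89	21.74	D1
MITE23	62	70.97	34.09	83.33	34.09	D1
MITE1	61	60.66	37.84	58.33	37.84	D2
MITE15	61	67.21	31.71	75.00	29.27	D2
MITE6	36	61.11	36.36	57.14	40.91	D2
MITE3	57	63.16	22.22	54.55	33.33	D2
MITE18	62	61.29	42.11	75.00	26.32	D2
MITE27	62	64.52	25.00	60.00	32.50	D2
Mito 5S	44	36.36	37.50	14.29	0.00	B2
Mito 16S	46	52.17	25.00	4.46	29.17	D2
Mito 18S	59	66.10	28.21	45.00	20.51	D2
Mito 23S1	375	46.93	16.48	14.82	20.46	D2
Mito 23S2	276	43.12	19.33	29.30	23.53	D2
Mito 23S3	209	37.32	24.36	23.19	19.23	B2
Mimi 5S	41	75.61	25.81	10.00	16.13	B2
Mimi 16S	39	45.76	33.33	16.17	14.82	B2
Mimi 18S	59	52.54	12.90	17.86	12.90	D2
Mimi 23S1	380	48.95	19.36	11.60	19.36	D2
Mimi 23S2	349	39.26	23.36	21.91	25.55	B2
Mimi 23S3	207	34.78	22.22	18.06	12.50	B2
WNV 3'-5	105	20.00	19.05	54.02	33.33	D1
DENV 3'-5	105	27.62	24.14	50.00	27.59	D1
JEV 3'-5	111	23.13	13.79	51.22	27.59	D1
YFV 3'-5	107	23.37	20.00	57.32	36.00	D1
5'-UTR Dengue	123	49.59	34.43	26.02	45.90	D2
Surrounding	92	52.17	43.75	30.68	31.25	B2
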