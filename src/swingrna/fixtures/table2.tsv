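label	n	loop	eloop	stem_gc	loop_gc	cluster
CVd IV	284	28.87	9.76	64.36	36.37	D1
TPMV	360	33.06	10.08	36.37	42.02	D2
TASV	360	28.33	11.77	60.02	34.31	D1
ASBV	359	29.81	7.48	63.49	42.06	D1
PTSV	247	32.39	17.50	40.12	31.25	D2
CSV	366	28.96	6.60	55.39	41.51	D2
PBCVd	315	31.43	31.32	71.76	37.37	D1
ADFVd	310	34.52	11.22	61.58	37.37	D1
CEVd	371	30.46	7.97	66.67	46.90	D1
HSVd	302	31.46	8.42	66.67	33.68	D1
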