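subject_id	gts_hp	imi_hp	lh_grip	rh_grip	months_post	lesion_volume	age	education	gender
1	0.60	0.70	22.34	20.34	174	115118	54	16	F
2	0.75	0.50	35	NA	172	258736	68	18	M
3	1.00	0.90	NA	NA	7	16978	31	12	M
4	0.83	0.90	37.67	27	112	166393	57	13	M
5	0.63	0.60	14.67	15	7	20190	69	12	F
6	0.73	0.70	30	20	14	76301	64	18	M
7	0.55	0.00	27.34	NA	22	171128	51	18	M
8	0.84	0.90	30.67	33	89	51780	79	21	M
9	0.80	0.60	20.67	16	47	82964	53	14	M
10	0.60	0.70	15	14	4	33183	59	14	F
11	0.93	0.70	17	13	73	37091	55	14	F
12	0.54	0.28	13.34	15.34	114	18528	80	12	F
13	0.83	0.50	26.34	NA	84	80020	47	13	F
14	0.88	0.70	47.67	37.34	24	47442	53	12	M
15	0.62	0.60	39.67	NA	31	179606	57	15	M
16	0.68	0.70	31	33	6	23141	55	12	M
17	1.00	0.60	37.67	31.67	53	20105	56	21	M
18	0.79	0.70	17.67	NA	8	71022	60	16	F
19	0.56	0.40	14.67	22	9	62204	32	18	F
20	0.93	0.50	24.34	29.67	68	94536	45	12	F
21	0.24	0.50	8	NA	11	303310	65	12	F
22	0.50	0.40	23.34	28	7	61198	71	12	F
23	0.66	0.70	28.34	NA	32	136576	46	12	F
24	0.75	0.90	33.34	26	24	52416	48	14	M
25	0.83	0.70	18	22	9	128897	54	12	F
26	0.76	0.90	35.67	34	7	51399	62	18	M
27	0.76	0.80	NA	NA	7	20790	50	12	F
28	0.85	0.70	41	NA	10	88046	31	13	M
29	0.90	0.70	33.34	4.34	65	27840	39	12	F
30	0.83	0.78	29	16	6	92744	48	12	M
31	0.70	0.70	NA	NA	31	200079	61	12	M
32	0.63	0.50	26.67	8.67	19	117809	41	12	F
33	0.79	0.40	22	24.67	40	5953	64	16	M
34	0.70	0.30	22.67	22.67	9	32684	64	13	F
35	0.95	0.40	46.34	54	32	337	55	16	M
36	0.55	0.90	28	30.34	31	32003	71	18	M
37	0.95	0.60	36	14.34	23	4095	63	18	M
38	0.87	0.70	42.34	14	10	27004	48	12	M
39	0.76	0.90	26.34	34	20	29052	58	12	M
40	0.87	0.40	31.34	35.67	17	102522	38	16	F
41	0.90	0.70	34.34	22.34	16	14660	53	18	M
42	0.80	0.70	21.67	20	4	9489	68	12	F
43	0.85	0.40	35.67	0	63	44493	46	18	F
44	0.89	0.90	19.67	17.67	17	16977	50	9	M
45	0.89	0.80	23.67	17.34	6	30414	68	12	F
46	0.65	0.60	NA	NA	7	16186	70	14	F
47	0.98	1.00	46	53.34	6	64375	45	12	M
48	0.74	0.60	26.67	0	9	56281	66	9	F
49	0.39	0.40	29.34	NA	12	225021	64	16	M
50	0.88	0.78	26	7.67	71	48459	53	13	F
51	0.90	0.86	NA	NA	17	93628	37	16	F
52	0.82	0.90	21.67	27.67	12	1869	67	12	F
53	0.98	0.80	36.67	32.34	12	17706	51	12	M
54	0.89	0.71	37.34	33.34	151	80532	55	16	F
55	0.85	0.78	30.67	NA	184	62530	60	13	F
56	0.87	0.64	23.67	10	30	87120	76	18	M
57	0.80	0.50	45.34	NA	161	96196	60	13	M
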