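name	ci_start_cm	ci_end_cm	left_marker	right_marker	n_qtls	n_studies	avg_pve	stresses
MQTL1B.3	65.69	65.96	BS00082577_51	RFL_Contig5937_1699	37	17	7.89	AS:2,D+H:7,DS:13,HS:3,PHS:2,SS:10
MQTL1D.4	90.8	91.96	BS00110144_51	AX-94558596	23	11	16.39	AS:7,D+H:2,DS:1,HS:5,SS:6,WS:3
MQTL2A.5	157.81	157.89	wsnp_Ex_c770_1514612	Excalibur_c3084_1843	44	14	10.7	AS:1,D+H:1,HS:27,SS:10,WS:5
MQTL2B.3	63.78	63.98	BobWhite_c31708_99	Excalibur_c4349_1050	84	34	10.12	AS:5,D+H:18,DS:10,HS:22,PHS:4,SS:20,WS:4
MQTL2B.4	66.49	67.8	Kukri_c34861_523	Kukri_c5497_312	13	12	8.01	AS:3,D+H:4,DS:2,HS:1,PHS:1,SS:2
MQTL2B.6	79.65	80.15	RAC875_c98387_130	Kukri_rep_c109981_150	16	9	11.76	D+H:2,DS:2,HS:1,PHS:1,SS:5,WS:5
MQTL2D.4	61.3	61.38	Xwmc453.1	Xcfd56	33	14	8.89	AS:1,D+H:1,DS:10,HS:6,PHS:1,SS:14
MQTL2D.5	77.81	78.25	Excalibur_rep_c107558_367	GENE-0875_887	25	12	21.66	AS:4,D+H:3,DS:3,HS:4,PHS:1,SS:10
MQTL3A.1	180.39	180.4	BobWhite_c2448_96	Excalibur_c47078_512	70	35	12.19	AS:6,D+H:9,DS:8,HS:10,PHS:13,SS:21,WS:3
MQTL3B.3	103.68	106.27	AX-94385276	Tdurum_contig80344_144	15	8	7.72	AS:1,DS:1,HS:3,SS:9,WS:1
MQTL3B.4	117.12	117.21	AX-95131037	BS00021992_51	107	25	8.78	AS:3,D+H:17,DS:16,HS:23,PHS:6,SS:37,WS:5
MQTL3B.5	124.66	125.5	AX-95020422	wsnp_Ra_c16264_24873670	18	7	9.03	AS:1,D+H:4,HS:2,SS:10,WS:1
MQTL3B.6	155.98	156.42	Ku_c30806_235	Xksug53	9	6	10.57	AS:4,D+H:1,HS:2,PHS:1,SS:1
MQTL3B.7	202.00	202.33	AX-94458019	BS00048754_51	16	9	11.78	D+H:6,HS:1,PHS:2,SS:6,WS:1
MQTL4A.2	115.90	116.03	Tdurum_contig1868_249	wsnp_BE405275A_Ta_1_1	79	32	12.95	AL:9,D+H:10,DS:18,HS:9,SS:18,WS:1
MQTL4A.5	154.63	154.63	BS00040648_51	RAC875_c1022_3059	16	9	9.11	AL:2,D+H:2,PHS:4,SS:8
MQTL5A.2	117.42	118.07	BS00100510_51	Tdurum_contig29286_319	69	24	10.11	AS:3,D+H:9,DS:26,HS:10,PHS:2,SS:14,WS:5
MQTL5B.5	121.79	122.3	Excalibur_rep_c104627_106	AX-95113708	54	25	9.25	D+H:11,DS:4,HS:14,PHS:1,SS:20,WS:4
MQTL6B.3	92.89	93.49	BS00088277_51	AX-94404945	51	22	8.47	AS:4,D+H:1,DS:23,HS:6,PHS:1,SS:16
MQTL7A.4	107.20	107.65	AX-95205723	AX-94402237	27	14	11.34	AS:5,D+H:1,DS:10,HS:3,PHS:1,SS:7
MQTL7A.5	122.91	123.40	AX-95260715	AX-94457603	47	22	10.52	AS:3,D+H:8,DS:21,HS:6,PHS:1,SS:8
MQTL7A.6	127.9	128.38	AX-94917420	AX-95206892	16	11	15.24	AS:2,D+H:4,DS:3,HS:1,PHS:1,SS:5
MQTL7A.7	130.35	130.83	AX-95226392	AX-94423924	13	10	11.6	D+H:2,DS:4,HS:2,PHS:1,SS:2,WS:2
MQTL7B.3	110.98	111.48	Tdurum_contig47317_100	BS00066647_51	61	24	9.71	AS:2,D+H:18,DS:8,HS:16,PHS:1,SS:9,WS:7
MQTL7B.4	124.39	125.17	BS00064367_51	IAAV8521	11	8	12.75	D+H:1,DS:2,HS:1,PHS:1,SS:5,WS:1
MQTL7D.1	32.05	34.75	Xgwm635	AX-94527430	13	10	11.64	D+H:1,DS:1,HS:5,PHS:1,SS:4,WS:1
MQTL7D.2	70.80	72.57	D_GA8KES401ANMPM_140	BobWhite_c5654_231	26	12	11.26	D+H:5,DS:5,HS:4,PHS:6,SS:4,WS:2
MQTL7D.3	81.29	81.8	D_contig12156_209	Kukri_c20975_765	18	13	11.94	AS:2,D+H:6,DS:1,HS:2,PHS:2,SS:5
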