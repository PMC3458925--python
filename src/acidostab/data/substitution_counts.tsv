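ap_np	S	Q	N	T	C	G	A	H	M	Y	F	V	L	P	I	W	D	E	K	R
S	1761	164	199	448	45	288	681	102	45	42	39	129	126	183	80	18	280	283	177	251
Q	109	945	82	100	6	101	211	117	47	42	32	88	146	51	54	19	148	360	167	305
N	165	97	1144	89	10	151	130	93	14	35	18	41	63	48	30	10	212	108	73	128
T	549	151	161	1908	49	175	488	95	71	68	67	368	258	139	198	28	211	264	160	286
C	64	16	17	49	411	27	160	12	23	11	20	130	63	12	54	7	7	6	6	27
G	313	142	203	150	26	6036	747	87	44	44	43	83	107	153	50	35	254	194	130	219
A	753	344	199	420	121	710	4986	169	165	161	127	733	552	364	299	64	335	561	293	528
H	72	117	67	56	7	76	120	951	19	135	59	48	90	53	26	19	86	95	83	157
M	39	64	24	75	23	36	131	23	775	49	93	192	499	17	220	31	24	53	37	77
Y	22	22	21	29	10	12	67	63	25	1134	263	61	111	16	55	42	18	29	14	54
F	34	34	29	59	11	46	112	54	81	343	1541	185	430	22	178	85	21	30	21	46
V	133	102	42	293	84	79	616	61	182	133	197	3271	1062	119	1264	48	66	147	103	173
L	107	164	64	208	64	112	454	74	448	209	433	872	5028	108	1100	110	75	131	101	246
P	189	77	58	122	15	150	407	52	30	35	27	128	116	2930	67	14	176	212	120	153
I	55	45	34	111	32	32	231	31	193	72	144	1065	1022	33	2214	28	26	57	39	97
W	11	18	7	10	10	18	40	16	17	109	98	29	86	10	25	384	8	17	19	30
D	219	226	299	146	19	266	350	121	19	38	29	85	88	147	40	22	2923	754	154	217
E	249	396	134	174	10	201	554	118	47	67	34	141	161	176	74	26	682	2830	263	431
K	125	203	102	122	9	131	245	61	33	35	24	88	88	108	48	21	171	235	1453	576
R	187	378	136	169	24	185	466	201	64	102	72	178	293	127	124	48	200	396	662	3400
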