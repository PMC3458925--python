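ap_residue	np_residue	count	ratio	mark
S	S	1761		.
S	Q	164	1.50	.
S	N	199	1.21	.
S	T	448	0.82	.
S	C	45	0.70	i
S	G	288	0.92	.
S	A	681	0.90	i
S	H	102	1.42	.
S	M	45	1.15	.
S	Y	42	1.91	.
S	F	39	1.15	.
S	V	129	0.97	.
S	L	126	1.18	.
S	P	183	0.97	.
S	I	80	1.45	.
S	W	18	1.64	.
S	D	280	1.28	.
S	E	283	1.14	.
S	K	177	1.42	.
S	R	251	1.34	b
Q	S	109	0.66	.
Q	Q	945		.
Q	N	82	0.85	.
Q	T	100	0.66	.
Q	C	6	0.38	.
Q	G	101	0.71	.
Q	A	211	0.61	i
Q	H	117	1.00	.
Q	M	47	0.73	.
Q	Y	42	1.91	.
Q	F	32	0.94	.
Q	V	88	0.86	.
Q	L	146	0.89	i
Q	P	51	0.66	.
Q	I	54	1.20	.
Q	W	19	1.06	.
Q	D	148	0.65	.
Q	E	360	0.91	i
Q	K	167	0.82	.
Q	R	305	0.81	.
N	S	165	0.83	.
N	Q	97	1.18	.
N	N	1144		.
N	T	89	0.55	.
N	C	10	0.59	.
N	G	151	0.74	i
N	A	130	0.65	i
N	H	93	1.39	.
N	M	14	0.58	.
N	Y	35	1.67	.
N	F	18	0.62	.
N	V	41	0.98	.
N	L	63	0.98	.
N	P	48	0.83	.
N	I	30	0.88	.
N	W	10	1.43	.
N	D	212	0.71	.
N	E	108	0.81	.
N	K	73	0.72	.
N	R	128	0.94	i
T	S	549	1.23	.
T	Q	151	1.51	.
T	N	161	1.81	.
T	T	1908		.
T	C	49	1.00	.
T	G	175	1.17	b
T	A	488	1.16	b
T	H	95	1.70	.
T	M	71	0.95	.
T	Y	68	2.34	.
T	F	67	1.14	.
T	V	368	1.26	b
T	L	258	1.24	b
T	P	139	1.14	.
T	I	198	1.78	.
T	W	28	2.80	.
T	D	211	1.45	.
T	E	264	1.52	b
T	K	160	1.31	.
T	R	286	1.69	b
C	S	64	1.42	b
C	Q	16	2.67	.
C	N	17	1.70	.
C	T	49	1.00	.
C	C	411		.
C	G	27	1.04	.
C	A	160	1.32	b
C	H	12	1.71	.
C	M	23	1.00	.
C	Y	11	1.10	.
C	F	20	1.82	.
C	V	130	1.55	b
C	L	63	0.98	.
C	P	12	0.80	.
C	I	54	1.69	b
C	W	7	0.70	.
C	D	7	0.37	.
C	E	6	0.60	.
C	K	6	0.67	.
C	R	27	1.13	b
G	S	313	1.09	.
G	Q	142	1.41	.
G	N	203	1.34	b
G	T	150	0.86	.
G	C	26	0.96	.
G	G	6036		.
G	A	747	1.05	b
G	H	87	1.14	b
G	M	44	1.22	.
G	Y	44	3.67	.
G	F	43	0.93	.
G	V	83	1.05	.
G	L	107	0.96	.
G	P	153	1.02	.
G	I	50	1.56	.
G	W	35	1.94	.
G	D	254	0.95	.
G	E	194	0.97	.
G	K	130	0.99	.
G	R	219	1.18	.
A	S	753	1.11	b
A	Q	344	1.63	b
A	N	199	1.53	b
A	T	420	0.86	i
A	C	121	0.76	i
A	G	710	0.95	.
A	A	4986		.
A	H	169	1.41	b
A	M	165	1.26	b
A	Y	161	2.40	.
A	F	127	1.13	b
A	V	733	1.19	.
A	L	552	1.22	.
A	P	364	0.89	i
A	I	299	1.29	.
A	W	64	1.60	b
A	D	335	0.96	.
A	E	561	1.01	.
A	K	293	1.20	b
A	R	528	1.13	.
H	S	72	0.71	.
H	Q	117	1.00	.
H	N	67	0.72	.
H	T	56	0.59	.
H	C	7	0.58	.
H	G	76	0.87	i
H	A	120	0.71	i
H	H	951		.
H	M	19	0.83	.
H	Y	135	2.14	.
H	F	59	1.09	.
H	V	48	0.79	.
H	L	90	1.22	b
H	P	53	1.02	.
H	I	26	0.84	.
H	W	19	1.19	.
H	D	86	0.71	.
H	E	95	0.81	.
H	K	83	1.36	.
H	R	157	0.78	i
M	S	39	0.87	.
M	Q	64	1.36	.
M	N	24	1.71	.
M	T	75	1.06	.
M	C	23	1.00	.
M	G	36	0.82	.
M	A	131	0.79	i
M	H	23	1.21	.
M	M	775		.
M	Y	49	1.96	.
M	F	93	1.15	.
M	V	192	1.05	b
M	L	499	1.11	b
M	P	17	0.57	.
M	I	220	1.14	b
M	W	31	1.82	.
M	D	24	1.26	.
M	E	53	1.13	.
M	K	37	1.12	.
M	R	77	1.20	b
Y	S	22	0.52	.
Y	Q	22	0.52	.
Y	N	21	0.60	.
Y	T	29	0.43	.
Y	C	10	0.91	.
Y	G	12	0.27	.
Y	A	67	0.42	.
Y	H	63	0.47	i
Y	M	25	0.51	.
Y	Y	1134		.
Y	F	263	0.77	.
Y	V	61	0.46	.
Y	L	111	0.53	.
Y	P	16	0.46	.
Y	I	55	0.76	.
Y	W	42	0.39	i
Y	D	18	0.47	.
Y	E	29	0.43	.
Y	K	14	0.40	.
Y	R	54	0.53	.
F	S	34	0.87	.
F	Q	34	1.06	.
F	N	29	1.61	.
F	T	59	0.88	.
F	C	11	0.55	.
F	G	46	1.07	.
F	A	112	0.88	i
F	H	54	0.92	.
F	M	81	0.87	.
F	Y	343	1.30	.
F	F	1541		.
F	V	185	0.94	i
F	L	430	0.99	.
F	P	22	0.81	.
F	I	178	1.24	b
F	W	85	0.87	.
F	D	21	0.72	.
F	E	30	0.88	.
F	K	21	0.88	.
F	R	46	0.64	.
V	S	133	1.03	.
V	Q	102	1.16	.
V	N	42	1.02	.
V	T	293	0.80	i
V	C	84	0.65	i
V	G	79	0.95	.
V	A	616	0.84	.
V	H	61	1.27	.
V	M	182	0.95	i
V	Y	133	2.18	.
V	F	197	1.06	b
V	V	3271		.
V	L	1062	1.22	b
V	P	119	0.93	.
V	I	1264	1.19	.
V	W	48	1.66	.
V	D	66	0.78	.
V	E	147	1.04	.
V	K	103	1.17	.
V	R	173	0.97	.
L	S	107	0.85	.
L	Q	164	1.12	b
L	N	64	1.02	.
L	T	208	0.81	i
L	C	64	1.02	.
L	G	112	1.05	.
L	A	454	0.82	.
L	H	74	0.82	i
L	M	448	0.90	i
L	Y	209	1.88	b
L	F	433	1.01	.
L	V	872	0.82	i
L	L	5028		.
L	P	108	0.93	.
L	I	1100	1.08	b
L	W	110	1.28	b
L	D	75	0.85	.
L	E	131	0.81	.
L	K	101	1.15	.
L	R	246	0.84	.
P	S	189	1.03	.
P	Q	77	1.51	.
P	N	58	1.21	.
P	T	122	0.88	.
P	C	15	1.25	.
P	G	150	0.98	.
P	A	407	1.12	b
P	H	52	0.98	.
P	M	30	1.76	.
P	Y	35	2.19	.
P	F	27	1.23	.
P	V	128	1.08	.
P	L	116	1.07	.
P	P	2930		.
P	I	67	2.03	.
P	W	14	1.40	.
P	D	176	1.20	.
P	E	212	1.20	.
P	K	120	1.11	.
P	R	153	1.20	.
I	S	55	0.69	.
I	Q	45	0.83	.
I	N	34	1.13	.
I	T	111	0.56	.
I	C	32	0.59	i
I	G	32	0.64	.
I	A	231	0.77	.
I	H	31	1.19	.
I	M	193	0.88	i
I	Y	72	1.31	.
I	F	144	0.81	i
I	V	1065	0.84	.
I	L	1022	0.93	i
I	P	33	0.49	.
I	I	2214		.
I	W	28	1.12	.
I	D	26	0.65	.
I	E	57	0.77	.
I	K	39	0.81	.
I	R	97	0.78	.
W	S	11	0.61	.
W	Q	18	0.95	.
W	N	7	0.70	.
W	T	10	0.36	.
W	C	10	1.43	.
W	G	18	0.51	.
W	A	40	0.63	i
W	H	16	0.84	.
W	M	17	0.55	.
W	Y	109	2.60	b
W	F	98	1.15	b
W	V	29	0.60	.
W	L	86	0.78	i
W	P	10	0.71	.
W	I	25	0.89	.
W	W	384		.
W	D	8	0.36	.
W	E	17	0.65	.
W	K	19	0.90	.
W	R	30	0.63	.
D	S	219	0.78	.
D	Q	226	1.53	.
D	N	299	1.41	.
D	T	146	0.69	.
D	C	19	2.71	.
D	G	266	1.05	.
D	A	350	1.04	.
D	H	121	1.41	.
D	M	19	0.79	.
D	Y	38	2.11	.
D	F	29	1.38	.
D	V	85	1.29	.
D	L	88	1.17	.
D	P	147	0.84	.
D	I	40	1.54	.
D	W	22	2.75	.
D	D	2923		.
D	E	754	1.11	.
D	K	154	0.90	.
D	R	217	1.09	.
E	S	249	0.88	.
E	Q	396	1.10	b
E	N	134	1.24	.
E	T	174	0.66	.
E	C	10	1.67	.
E	G	201	1.04	.
E	A	554	0.99	.
E	H	118	1.24	.
E	M	47	0.89	.
E	Y	67	2.31	.
E	F	34	1.13	.
E	V	141	0.96	.
E	L	161	1.23	.
E	P	176	0.83	.
E	I	74	1.30	.
E	W	26	1.53	.
E	D	682	0.90	.
E	E	2830		.
E	K	263	1.12	.
E	R	431	1.09	.
K	S	125	0.71	.
K	Q	203	1.22	.
K	N	102	1.40	.
K	T	122	0.76	.
K	C	9	1.50	.
K	G	131	1.01	.
K	A	245	0.84	i
K	H	61	0.73	.
K	M	33	0.89	.
K	Y	35	2.50	.
K	F	24	1.14	.
K	V	88	0.85	.
K	L	88	0.87	.
K	P	108	0.90	.
K	I	48	1.23	.
K	W	21	1.11	.
K	D	171	1.11	.
K	E	235	0.89	.
K	K	1453		.
K	R	576	0.87	i
R	S	187	0.75	i
R	Q	378	1.24	b
R	N	136	1.06	b
R	T	169	0.59	i
R	C	24	0.89	i
R	G	185	0.84	.
R	A	466	0.88	.
R	H	201	1.28	b
R	M	64	0.83	i
R	Y	102	1.89	.
R	F	72	1.57	.
R	V	178	1.03	.
R	L	293	1.19	.
R	P	127	0.83	.
R	I	124	1.28	.
R	W	48	1.60	.
R	D	200	0.92	.
R	E	396	0.92	.
R	K	662	1.15	b
R	R	3400		.
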