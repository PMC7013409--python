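# Reference residue-pair binding-propensity (RAIR) matrix estimated on a
# curated docking-benchmark dimer set. rair[i][j] = AIR_ij / AR_j; values >= 1
# mark high binding propensity of partner j at interfaces of residue i.
i\j	A	L	I	V	G	K	R	D	E	H	N	Q	S	T	C	M	Y	W	F	P
A	0.47	1.58	1.80	1.24	1.07	0.58	1.00	0.60	0.61	1.22	0.99	0.99	0.79	1.09	2.31	1.88	2.83	2.52	2.74	0.44
L	0.82	1.17	2.68	1.43	0.80	0.62	0.96	0.46	0.50	1.35	0.83	0.99	0.73	0.94	2.96	2.75	2.57	3.44	3.03	0.61
I	0.75	2.16	1.38	1.25	0.93	0.61	0.97	0.61	0.52	1.53	0.90	1.09	0.66	0.67	2.76	1.31	2.50	3.39	3.36	0.59
V	0.74	1.65	1.79	0.89	0.99	0.53	1.24	0.71	0.54	1.19	0.98	0.91	0.69	0.93	1.98	2.00	3.16	2.87	2.29	0.59
G	0.92	1.33	1.90	1.42	0.56	0.62	1.15	0.66	0.53	1.01	1.10	1.02	0.59	1.13	3.48	2.12	2.70	3.76	2.33	0.53
K	0.62	1.28	1.56	0.95	0.78	0.19	0.76	1.35	1.43	1.04	0.91	0.76	0.91	0.85	2.08	1.28	2.88	2.66	1.99	0.57
R	0.63	1.16	1.45	1.30	0.84	0.44	0.41	1.23	1.04	1.17	1.06	1.02	0.76	0.91	2.07	1.64	2.68	3.83	2.12	0.65
D	0.58	0.88	1.43	1.16	0.76	1.23	1.93	0.28	0.57	1.18	1.09	1.10	0.83	0.95	1.48	1.02	2.85	2.28	2.00	0.45
E	0.63	0.99	1.28	0.93	0.64	1.38	1.71	0.60	0.28	1.40	1.06	0.93	0.97	1.08	1.14	2.20	2.08	2.14	2.09	0.62
H	0.74	1.59	2.22	1.21	0.72	0.59	1.14	0.73	0.82	0.50	1.10	0.83	0.71	0.98	3.07	2.10	2.19	2.75	2.23	0.64
N	0.73	1.18	1.59	1.21	0.95	0.63	1.25	0.83	0.76	1.34	0.54	1.12	0.75	1.22	1.41	1.23	2.85	2.26	1.76	0.66
Q	0.75	1.46	1.99	1.16	0.90	0.54	1.25	0.86	0.69	1.04	1.16	0.42	0.75	1.07	1.35	1.62	2.37	2.46	2.43	0.80
S	0.77	1.37	1.54	1.12	0.67	0.82	1.19	0.82	0.91	1.14	0.99	0.95	0.37	1.05	3.53	2.00	2.12	2.92	2.16	0.68
T	0.82	1.36	1.19	1.16	0.98	0.59	1.08	0.73	0.78	1.20	1.23	1.04	0.81	0.51	1.10	1.68	2.85	3.61	2.21	0.66
C	0.76	1.88	2.17	1.09	1.34	0.64	1.09	0.50	0.37	1.67	0.63	0.58	1.20	0.48	0.63	2.49	2.36	2.78	3.09	0.63
M	0.74	2.08	1.23	1.32	0.97	0.47	1.03	0.41	0.84	1.36	0.65	0.83	0.81	0.88	2.97	1.19	2.54	1.86	3.80	0.73
Y	0.80	1.41	1.70	1.50	0.89	0.76	1.22	0.83	0.57	1.03	1.10	0.88	0.62	1.08	2.03	1.84	0.70	3.03	2.82	0.91
W	0.62	1.63	1.99	1.18	1.08	0.61	1.51	0.57	0.51	1.11	0.75	0.79	0.74	1.19	2.07	1.16	2.62	1.67	1.81	0.92
F	0.83	1.78	2.43	1.16	0.82	0.56	1.03	0.62	0.62	1.11	0.72	0.96	0.67	0.90	2.84	2.94	3.01	2.23	1.12	0.84
P	0.49	1.31	1.58	1.11	0.69	0.59	1.15	0.52	0.68	1.18	0.99	1.16	0.78	0.98	2.13	2.09	3.59	4.17	3.09	0.35
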