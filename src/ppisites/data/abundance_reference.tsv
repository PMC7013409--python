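# Residue counts and abundances over whole proteins (w) and the protein
# surface (s) of the reference dimer set; ar columns are printed at 3 dp.
aa	n_whole	ar_whole	n_surface	ar_surface
A	9558	0.071	3599	0.058
L	11587	0.087	2913	0.047
I	6700	0.050	1462	0.024
V	9407	0.070	2207	0.036
G	9930	0.074	4839	0.078
K	8155	0.061	5656	0.092
R	6093	0.046	3820	0.062
D	7561	0.057	4823	0.078
E	8667	0.065	5700	0.092
H	3128	0.023	1448	0.023
N	5812	0.043	3673	0.060
Q	5478	0.041	3396	0.055
S	9575	0.072	5498	0.089
T	8345	0.062	4069	0.066
C	2742	0.020	518	0.008
M	2785	0.021	791	0.013
Y	4811	0.036	1812	0.029
W	2035	0.015	552	0.009
F	5132	0.038	1101	0.018
P	6294	0.047	3845	0.062
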