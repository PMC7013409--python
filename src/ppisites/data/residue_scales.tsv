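# Per-residue hydrophobicity (Fauchere-Pliska-style) and polarity scales
# used as feature inputs and for propensity comparisons.
aa	hydrophobicity	polarity
A	0.62	8.1
R	-2.53	10.5
N	-0.78	11.6
D	-0.9	13.0
C	0.29	5.5
Q	-0.85	10.5
E	-0.74	12.3
G	0.48	9.0
H	-0.4	10.4
I	1.38	5.2
L	1.06	4.9
K	-1.5	11.3
M	0.64	5.7
F	1.19	5.2
P	0.12	8.0
S	-0.18	9.2
T	-0.05	8.6
W	0.81	5.4
Y	0.26	6.2
V	1.08	5.9
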