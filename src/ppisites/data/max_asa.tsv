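# Maximum solvent-accessible surface area per residue type (A^2),
# used to convert ASA to relative ASA.
aa	max_asa
A	106
R	248
N	157
D	163
C	135
Q	198
E	194
G	84
H	184
I	169
L	164
K	205
M	188
F	197
P	136
S	130
T	142
W	227
Y	222
V	142
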