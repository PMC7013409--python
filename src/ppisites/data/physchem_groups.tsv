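# 24 physicochemical properties; each splits the 20 standard residues into
# three groups (0/1/2) that are one-hot encoded into a 72-dim vector.
# Group labels are anchored to the canonical printed alanine encoding; for
# the remaining residues the grouping follows standard composition/transition/
# distribution attribute classes plus rank-tertiles of documented numeric
# scales and small-molecule descriptors of the free amino acids.
property	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
hydrophobicity_class	1	0	0	0	2	0	0	1	1	2	2	0	2	2	1	1	1	2	1	2
vdw_volume_class	0	2	1	0	0	1	1	0	2	1	1	2	2	2	0	0	0	2	2	1
polarity_class	1	2	2	2	0	2	2	1	2	0	0	2	0	0	1	1	1	0	0	0
polarizability_class	0	2	1	0	1	1	1	0	2	1	1	2	2	2	1	0	0	2	2	1
charge_class	0	2	0	1	0	0	1	0	0	0	0	2	0	0	0	0	0	0	0	0
secondary_structure_class	0	0	2	2	1	0	0	2	0	1	0	0	0	1	2	2	1	1	1	1
solvent_accessibility_class	0	1	1	1	0	1	1	0	2	0	0	1	2	0	2	2	2	0	2	0
polarity_scale_tertile	0	1	1	1	2	1	1	0	1	2	2	1	2	2	0	0	0	2	0	2
hydrophobicity_scale_tertile	1	2	2	2	0	2	2	0	2	1	1	2	1	1	0	0	0	1	0	1
max_asa_tertile	1	0	2	2	1	0	0	1	2	2	2	0	2	0	1	1	1	0	0	1
interior_tendency_tertile	1	0	0	0	2	0	0	1	1	2	2	0	2	2	0	1	1	2	1	2
mol_weight_tertile	1	0	2	2	1	2	0	1	0	2	2	2	0	0	1	1	1	0	0	1
tpsa_tertile	2	1	1	1	2	1	1	2	1	2	2	1	0	2	2	0	0	0	0	0
logp_tertile	1	0	0	0	1	0	1	0	1	2	2	1	2	2	1	0	0	2	2	2
hbond_donors_tertile	1	0	0	2	2	0	2	1	2	1	1	2	1	1	1	0	0	0	0	2
hbond_acceptors_tertile	2	1	1	0	0	1	0	2	0	2	2	0	1	2	2	1	1	0	1	2
rotatable_bonds_tertile	2	1	0	0	2	1	1	2	0	0	0	1	1	0	2	2	2	1	1	2
ring_atoms_tertile	2	0	0	2	2	0	2	2	1	2	0	2	0	1	1	0	1	1	1	1
heavy_atoms_tertile	0	2	1	1	0	2	1	0	2	1	1	2	1	2	0	0	0	2	2	0
aromatic_atoms_tertile	1	2	2	1	1	2	1	1	0	1	2	1	2	0	2	0	0	0	0	0
fraction_csp3_tertile	2	2	1	1	2	2	2	1	1	0	0	0	0	1	0	2	0	1	1	0
labute_asa_tertile	2	1	0	0	2	0	0	2	1	0	0	1	1	1	2	2	2	1	1	2
molar_refractivity_tertile	0	2	0	0	1	1	1	0	2	1	1	2	2	2	0	0	0	2	2	1
heteroatoms_tertile	1	0	0	0	2	0	0	1	0	1	1	2	2	1	1	2	2	2	0	1
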