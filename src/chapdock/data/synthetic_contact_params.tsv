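# Synthetic default contact-parameter table (NOT a published statistical
# potential).  Constructed for this package as a documented stand-in:
# column 2 is a hydrophobicity scale rescaled to [0, 1]; column 3 is an
# approximate Ca-bead diameter (Angstrom) by residue size.  The energy model
# combines them as eps_ij = -lambda * h_i * h_j + e0 (lambda = 0.6 kcal/mol,
# e0 = 0.2 kcal/mol by default), so hydrophobic pairs attract and polar pairs
# are mildly repulsive.  Replace with a fitted table for production systems.
# residue	hydrophobicity	diameter
A	0.700	5.0
C	0.778	5.5
D	0.111	5.6
E	0.111	6.0
F	0.811	6.4
G	0.456	4.5
H	0.144	6.1
I	1.000	6.2
K	0.067	6.4
L	0.922	6.2
M	0.711	6.2
N	0.111	5.7
P	0.322	5.6
Q	0.111	6.0
R	0.000	6.6
S	0.411	5.2
T	0.422	5.6
V	0.967	5.9
W	0.400	6.8
Y	0.356	6.5
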