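# Synthetic single-residue heptad propensity table (COILS-style log-odds).
# Authored for this package: favors hydrophobic residues at core positions
# a/d and charged/polar residues at b,c,e,f,g; not trained on any external
# coiled-coil database.
# window	28
# threshold	18.0
aa	a	b	c	d	e	f	g
A	0.8	0.4	0.4	0.8	0.4	0.4	0.4
C	0.0	-0.3	-0.3	0.0	-0.3	-0.3	-0.3
D	-0.8	0.2	0.2	-0.8	0.2	0.2	0.2
E	-0.4	0.6	0.6	-0.4	0.6	0.6	0.6
F	0.6	-0.3	-0.3	0.6	-0.3	-0.3	-0.3
G	-1.5	-1.0	-1.0	-1.5	-1.0	-1.0	-1.0
H	-0.3	0.0	0.0	-0.3	0.0	0.0	0.0
I	1.5	-0.2	-0.2	1.5	-0.2	-0.2	-0.2
K	-0.4	0.6	0.6	-0.4	0.6	0.6	0.6
L	2.0	0.0	0.0	2.0	0.0	0.0	0.0
M	1.5	0.0	0.0	1.5	0.0	0.0	0.0
N	-0.5	0.2	0.2	-0.5	0.2	0.2	0.2
P	-3.0	-2.5	-2.5	-3.0	-2.5	-2.5	-2.5
Q	-0.2	0.5	0.5	-0.2	0.5	0.5	0.5
R	-0.4	0.4	0.4	-0.4	0.4	0.4	0.4
S	-0.5	0.1	0.1	-0.5	0.1	0.1	0.1
T	-0.4	0.0	0.0	-0.4	0.0	0.0	0.0
V	1.2	-0.3	-0.3	1.2	-0.3	-0.3	-0.3
W	0.0	-0.5	-0.5	0.0	-0.5	-0.5	-0.5
Y	0.2	-0.1	-0.1	0.2	-0.1	-0.1	-0.1
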