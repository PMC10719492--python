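aa	sidechain_atoms	compactness	charge	hydrophobicity
A	1	1	0	0.62
C	2	2	0	0.29
D	4	3	-1	-0.90
E	5	4	-1	-0.74
F	7	5	0	1.19
G	0	0	0	0.48
H	6	4	0.5	-0.40
I	4	3	0	1.38
K	5	5	1	-1.50
L	4	3	0	1.06
M	4	4	0	0.64
N	4	3	0	-0.78
P	3	3	0	0.12
Q	5	4	0	-0.85
R	7	6	1	-2.53
S	2	2	0	-0.18
T	3	2	0	-0.05
V	3	2	0	1.08
W	10	6	0	0.81
Y	8	6	0	0.26
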