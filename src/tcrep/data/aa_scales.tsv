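residue	hydropathy	bulkiness	polarity
A	1.8	11.50	8.1
R	-4.5	14.28	10.5
N	-3.5	12.82	11.6
D	-3.5	11.68	13.0
C	2.5	13.46	5.5
Q	-3.5	14.45	10.5
E	-3.5	13.57	12.3
G	-0.4	3.40	9.0
H	-3.2	13.69	10.4
I	4.5	21.40	5.2
L	3.8	21.40	4.9
K	-3.9	15.71	11.3
M	1.9	16.25	5.7
F	2.8	19.80	5.2
P	-1.6	17.43	8.0
S	-0.8	9.47	9.2
T	-0.7	15.77	8.6
W	-0.9	21.67	5.4
Y	-1.3	18.03	6.2
V	4.2	21.57	5.9
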