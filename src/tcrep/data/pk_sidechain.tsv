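residue	pk	kind
R	12.5	basic
H	6.5	basic
K	10.8	basic
D	3.9	acidic
E	4.1	acidic
C	8.5	acidic
Y	10.1	acidic
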