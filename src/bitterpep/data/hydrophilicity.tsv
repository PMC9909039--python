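residue	value
A	-0.5
C	-1.0
D	3.0
E	3.0
F	-2.5
G	0.0
H	-0.5
I	-1.8
K	3.0
L	-1.8
M	-1.3
N	0.2
P	0.0
Q	0.2
R	3.0
S	0.3
T	-0.4
V	-1.5
W	-3.4
Y	-2.3
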