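# Karplus PA, Schulz GE (1985) Prediction of chain flexibility in proteins.
# Naturwissenschaften 72:212-213. Normalized backbone B-value scale
# (1.0 = average flexibility); windowed means > 1 flag flexible regions.
residue	value
A	1.041
R	1.038
N	1.117
D	1.033
C	0.960
Q	1.165
E	1.094
G	1.142
H	0.982
I	1.002
L	0.967
K	1.093
M	0.947
F	0.930
P	1.055
S	1.169
T	1.073
W	0.925
Y	0.961
V	0.982
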