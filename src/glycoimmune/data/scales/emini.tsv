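# Emini EA, Hughes JV, Perlow DS, Boger J (1985) Induction of hepatitis A
# virus-neutralizing antibody by a virus-specific synthetic peptide.
# J Virol 55:836-839. Fractional surface probabilities; the hexapeptide
# surface probability is the product of six values times 0.37^-6.
residue	value
A	0.49
R	0.95
N	0.81
D	0.78
C	0.26
Q	0.84
E	0.84
G	0.48
H	0.66
I	0.34
L	0.40
K	0.97
M	0.48
F	0.42
P	0.75
S	0.65
T	0.70
W	0.51
Y	0.76
V	0.36
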