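# Chou-Fasman conformational parameters, transcribed from
# Chou PY, Fasman GD (1978) "Prediction of the secondary structure of proteins
# from their amino acid sequence", Adv Enzymol Relat Areas Mol Biol 47:45-148.
# Pa = alpha-helix propensity, Pb = beta-sheet propensity, Pt = beta-turn
# propensity; 1.0 is indifferent. Anchors: N/G Pt = 1.56, I Pt = 0.47.
# residue	Pa	Pb	Pt
A	1.42	0.83	0.66
R	0.98	0.93	0.95
N	0.67	0.89	1.56
D	1.01	0.54	1.46
C	0.70	1.19	1.19
Q	1.11	1.10	0.98
E	1.51	0.37	0.74
G	0.57	0.75	1.56
H	1.00	0.87	0.95
I	1.08	1.60	0.47
L	1.21	1.30	0.59
K	1.16	0.74	1.01
M	1.45	1.05	0.60
F	1.13	1.38	0.60
P	0.57	0.55	1.52
S	0.77	0.75	1.43
T	0.83	1.19	0.96
W	1.08	1.37	0.96
Y	0.69	1.47	1.14
V	1.06	1.70	0.50
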