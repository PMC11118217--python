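residue	dndc_mL_per_g	mass_g_per_mol	source
A	0.167	71.08	McMeekin1964/Zhao2011
R	0.206	156.19	McMeekin1964/Zhao2011
N	0.192	114.10	McMeekin1964/Zhao2011
D	0.197	115.09	McMeekin1964/Zhao2011
C	0.206	103.14	McMeekin1964/Zhao2011
Q	0.186	128.13	McMeekin1964/Zhao2011
E	0.183	129.12	McMeekin1964/Zhao2011
G	0.175	57.05	McMeekin1964/Zhao2011
H	0.219	137.14	McMeekin1964/Zhao2011
I	0.179	113.16	McMeekin1964/Zhao2011
L	0.173	113.16	McMeekin1964/Zhao2011
K	0.181	128.17	McMeekin1964/Zhao2011
M	0.204	131.19	McMeekin1964/Zhao2011
F	0.244	147.18	McMeekin1964/Zhao2011
P	0.165	97.12	McMeekin1964/Zhao2011
S	0.170	87.08	McMeekin1964/Zhao2011
T	0.172	101.10	McMeekin1964/Zhao2011
W	0.277	186.21	McMeekin1964/Zhao2011
Y	0.240	163.18	McMeekin1964/Zhao2011
V	0.172	99.13	McMeekin1964/Zhao2011
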