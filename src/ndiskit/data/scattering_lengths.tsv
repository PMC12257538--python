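# Coherent bound neutron scattering lengths (Sears compilation)
# label	b_coh (fm)
H	-3.739
D	6.671
C	6.646
N	9.36
O	5.803
F	5.654
Na	3.63
P	5.13
S	2.847
Cl	9.577
K	3.67
Br	6.795
I	5.28
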