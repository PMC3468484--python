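quantity	unit	2X
mu	1/h	0.019
H_RNA	molecules/cell	n.m.
L_RNA	molecules/cell	n.m.
H	molecules/cell	4.2x10^6
L	molecules/cell	2.0x10^6
LL	molecules/cell	<0.1x10^6
HL	molecules/cell	7.3x10^6
HH	molecules/cell	<0.1x10^6
HHL	molecules/cell	<0.1x10^6
LHHL	molecules/cell	3.7x10^6
qL	molecules/cell/h	2.2x10^6
qLL	molecules/cell/h	3.2x10^6
qmAb	molecules/cell/h	0.9x10^6
qHL	molecules/cell/h	0.9x10^6
H_RNA_decay	1/h	n.m.
L_RNA_decay	1/h	n.m.
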