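quantity	unit	2N2	2P	4O	4R
mu	1/h	0.020	0.025	0.036	0.025
H_RNA	molecules/cell	781	250	71	137
L_RNA	molecules/cell	60611	41165	741	550
H	molecules/cell	4.7x10^6	2.5x10^6	<0.1x10^6	2.3x10^6
L	molecules/cell	1.7x10^6	1.4x10^6	1.1x10^6	1.4x10^6
LL	molecules/cell	1.2x10^6	0.8x10^6	0.7x10^6	0.5x10^6
HL	molecules/cell	160x10^6	60x10^6	10x10^6	>0.1x10^6
HH	molecules/cell	<0.1x10^6	<0.1x10^6	<0.1x10^6	<0.1x10^6
HHL	molecules/cell	<0.1x10^6	<0.1x10^6	<0.1x10^6	<0.1x10^6
LHHL	molecules/cell	12x10^6	2.6x10^6	1.4x10^6	2.3x10^6
qL	molecules/cell/h	37x10^6	1.6x10^6	0.4x10^6	<0.1x10^6
qLL	molecules/cell/h	12x10^6	1.0x10^6	0.1x10^6	<0.1x10^6
qmAb	molecules/cell/h	2.9x10^6	0.4x10^6	0.1x10^6	<0.1x10^6
qHL	molecules/cell/h	11x10^6	0.7x10^6	0.1x10^6	<0.1x10^6
H_RNA_decay	1/h	<0.025	0.400	0.038	0.043
L_RNA_decay	1/h	<0.025	0.109	0.026	0.026
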