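res_a	res_b	rate
V	I	275
V	L	168
V	A	61
V	F	22
L	I	82
L	A	16
L	M	16
L	F	65
L	W	4
L	Y	4
L	T	3
I	F	10
I	A	8
I	M	4
G	A	46
F	A	7
T	A	22
S	A	6
Y	F	20
Y	W	18
Y	H	3
F	W	5
F	M	4
T	V	6
T	G	4
T	S	7
G	S	3
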