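# key residues for FK506 binding / PPIase activity in human FKBP12
# position	residue
27	Y
37	F
38	D
43	R
47	F
55	E
56	V
57	I
60	W
82	A
83	Y
88	H
92	I
100	F
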