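# key residues for cyclosporin A binding / PPIase activity in human cyclophilin A
# position	residue
54	H
55	R
60	F
111	Q
113	F
121	W
126	H
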