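# family=FKBP
# positions=27,37,38,43,47,55,56,57,60,82,83,88,92,100
OsFKBP12	AtFKBP12	C	"	W	A/E	"	S/A	"	"	"	"	"	F	"	"	64/64	86
OsFKBP13	AtFKBP13	"	"	"	"	L	"	"	"	"	"	"	A	"	"	86/86	100
OsFKBP15-1	AtFKBP15-1	"	"	"	"	I	Q	"	"	"	G	"	S	"	"	71/71	100
OsFKBP15-2	AtFKBP15-2	"	"	"	"	F	Q	"	"	"	G	"	S	"	"	71/71	100
	AtFKBP15-3	"	"	"	K	Y	K	"	"	L	G	"	-	"	"	-/57	
OsFKBP16-1	AtFKBP16-1	"	V	H	Q	V	"/D	M/V	"	L	G	"	P	L	"	36/29	86
OsFKBP16-2	AtFKBP16-2	"	"	"	"	L	K	I/"	L/"	L	"	"	G	"	Y	50/64	86
OsFKBP16-3	AtFKBP16-3	"	"	"	K	Y	Q	"	"	L	"	F	A	V	"	50/50	100
OsFKBP16-4	AtFKBP16-4	"	"	M	G	Y	"	"	L	L	"	"	V	A/L	"	50/50	93
OsFKBP17-1	AtFKBP17-1	"	"	"	H	"	N/K	"	"	I	G	"	Q	P	"	57/57	93
OsFKBP17-2	AtFKBP17-2	L	V	V	G/K	L	P	Y	T/S	M/L	G	F	A	V/"	Y	0/7	71
	AtFKBP17-3	V	V	"	K	L	P	Y	S	L	G	F	Q	"	Y	-/14	
OsFKBP18	AtFKBP18	F	L	A	I	Y	P	G	K	K	G	"	M	"	L	14/14	100
OsFKBP19	AtFKBP19	W	"	E	D	"	Q/"	"	"	F	G	"	Y	G	"	43/50	93
OsFKBP20-1a	AtFKBP20-1	"	"	"	D	"	A/S	"	"	"	"	"	S	"	"	79/79	93
OsFKBP20-1b		"	"	"	D	"	T	"	"	"	"	"	S	"	"	7/-	
OsFKBP20-2	AtFKBP20-2	"	I	"	Q	I	T/A	L	V	F	G	P	P	F	"	21/21	93
OsFKBP42a	AtFKBP42	"	"	E	E	I	K	E	M/L	L	G/"	"	S	V	Y	21/29	86
OsFKBP42b		"	"	E	E	I	K	Q	M	L	G	"	S	V	Y	21/29	
	AtFKBP43	"	"	"	E	L	N	"	"	L	G	"	G	K	Y	-/43	
OsFKBP44		"	V	"	S	C	"	"	"	"	G	"	R	"	"	64/-	
OsFKBP46		F	"	V	N	"	N	"	M	L	"	I	S	"	"	43/-	
OsFKBP53	AtFKBP53	"	V/"	E/"	E/K	"	K/S	"	"	"	C/G	"	I/A	V/"	Y/"	43/64	44
OsFKBP57		"	V	S	-	I	F	F	C	F	G	F	R	V	V	7/-	
OsFKBP58		"	"	"	"	"	"	"	"	"	G	"	R	"	"	79/-	
OsFKBP59		"	I	"	N	H	"	"	"	"	G	"	T	"	Y	57/-	
OsFKBP62a	AtFKBP62	"	"	"	"	"	Q	"	"	"	"	"	S	"/-	"	86/79	93
OsFKBP62b	AtFKBP62	"	"	"	"	"	"/Q	"	"	"	"	"	S	"/-	"	93/79	86
OsFKBP62c	AtFKBP62	"	"	"	"	"	Q	"	"	"	"	"	S	"/-	"	86/79	93
	AtFKBP65	"	"	"	"	"	H	"	"	"	"	"	S	-	"	-/79	
OsFKBP72	AtFKBP72	"	Y	"	N	"	L	"	P	F	"	"	R	V	W	43/43	100
OsFKBP73		F	"	V	N	E	D	"	M	F	T	M	S	"	"	36/-	
%column	79/77	68/73	57/64	32/27	43/36	25/14	75/73	68/68	46/36	46/46	82/82	0/0	46/50	64/64
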