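# family=CYP
# positions=54,55,60,111,113,121,126
OsCYP17		S	Q	I	"	"	"	Y	43/-	
OsCYP18-1	AtCYP18-1	"	"	"	"	"	H	Y	71/71	100
OsCYP18-2	AtCYP18-2	"	"	"	"	"	S	"	86/86	100
	AtCYP18-3	"	"	"	"	"	"	"	-/100	
OsCYP18-4	AtCYP18-4	"	"	"	"	"	"	"	-/100	
	AtCYP19-1	"	"	"	"	"	"	"	-/100	
OsCYP19-2	AtCYP19-2	"	"	"	"	"	"	"	100/100	100
OsCYP19-3	AtCYP19-3	"	"	"	"	"	"	"	100/100	100
OsCYP19-4	AtCYP19-4	"	"	"	"	"	R/"	"	88/100	88
OsCYP20-1	AtCYP20-1	"	"	"	"	"	"	"	100/100	100
OsCYP20-2	AtCYP20-2	"	"	"	"	"	"	"	100/100	100
OsCYP20-3	AtCYP20-3	"	"	"	"	"	"	"	100/100	100
OsCYP21-1	AtCYP21-1	"	"	"	"	"	"	"	100/100	100
	AtCYP21-2	"	"	"	"	"	"	"	-/100	
	AtCYP21-3	S	"	K	E	"	D	L	-/29	
OsCYP21-4	AtCYP21-4	R/Q	H/"	F/Y	D/E	L	D	L	0/14	43
OsCYP22	AtCYP22	"	"	"	"	"	"	"	100/100	100
OsCYP23	AtCYP23	F	"	"	S	S	H	Y	29/29	100
	AtCYP26-1	D	H	L	"	O	Q	"	-/29	
OsCYP26-2	AtCYP26-2	V	K	Y	E	V	E	A/V	0/0	86
OsCYP28	AtCYP28	"	K	Q	E	L	E/Q	N	14/0	86
OsCYP37	AtCYP37	Y	T	L	"	"	F	F	29/29	100
OsCYP38	AtCYP38	F	"	"	"	"	I	Y	57/57	100
OsCYP40a	AtCYP40	"	"	I	"	"	H	"	71/71	100
OsCYP40b	AtCYP40	"	"	I	"	"	H	"	71/71	100
OsCYP57	AtCYP57	"	"	"	"	"	"	N/"	86/100	86
OsCYP59a	AtCYP59	R/Q	K	Q	"	Y	Y	"	29/29	86
OsCYP59b	AtCYP59	R/Q	K	Q	"	Y	Y	"	29/29	86
OsCYP63	AtCYP63	"	F/"	M/"	"	"	H	"	57/86	71
OsCYP65	AtCYP65	"	"	"	"	"	H	"	86/86	100
OsCYP71	AtCYP71	"	"	"	"	"	"	"	100/100	100
OsCYP95	AtCYP95	"	"	"	"/H	"/H	R/Q	S/N	57/43	43
%column	71/77	79/79	72/69	82/79	71/71	38/52	62/69
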