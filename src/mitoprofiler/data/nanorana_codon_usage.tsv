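AminoAcid	Codon	N_parkeri	N_ventripunctata	N_pleskei
Phe	UUU	156	148	165
Phe	UUC	103	102	91
Leu	UUA	118	123	117
Leu	UUG	26	30	44
Leu	CUU	143	142	137
Leu	CUC	137	134	130
Leu	CUA	140	128	132
Leu	CUG	50	58	58
Ile	AUU	190	204	212
Ile	AUC	112	102	88
Met	AUA	121	125	119
Met	AUG	58	60	62
Val	GUU	71	71	84
Val	GUC	43	52	47
Val	GUA	59	66	73
Val	GUG	38	24	21
Ser	UCU	62	67	71
Ser	UCC	79	72	68
Ser	UCA	70	78	78
Ser	UCG	16	7	9
Pro	CCU	33	34	40
Pro	CCC	91	98	83
Pro	CCA	58	61	62
Pro	CCG	25	18	19
Thr	ACU	80	73	86
Thr	ACC	97	95	82
Thr	ACA	109	100	112
Thr	ACG	13	18	8
Ala	GCU	72	69	78
Ala	GCC	152	148	145
Ala	GCA	69	69	73
Ala	GCG	19	25	18
Tyr	UAU	63	61	60
Tyr	UAC	43	47	50
Stop	UAA*	3	3	3
Stop	UAG*	1	1	1
His	CAU	34	28	34
His	CAC	67	73	67
Gln	CAA	75	78	77
Gln	CAG	18	13	14
Asn	AAU	63	69	63
Asn	AAC	62	49	54
Lys	AAA	69	73	64
Lys	AAG	15	18	23
Asp	GAU	30	31	33
Asp	GAC	44	40	37
Glu	GAA	61	57	62
Glu	GAG	29	32	29
Cys	UGU	11	17	15
Cys	UGC	18	12	13
Trp	UGA	84	88	86
Trp	UGG	25	22	25
Arg	CGU	14	11	12
Arg	CGC	18	23	20
Arg	CGA	35	33	31
Arg	CGG	7	10	10
Ser	AGU	25	23	25
Ser	AGC	30	33	29
Stop	AGA*	1	1	1
Stop	AGG*	1	1	1
Gly	GGU	36	42	47
Gly	GGC	74	69	61
Gly	GGA	50	52	48
Gly	GGG	58	63	67
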