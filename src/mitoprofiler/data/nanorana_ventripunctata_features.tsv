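Gene	Strand	From	To	Size	Start	Stop	Intergenic
tRNA-Leu1	H	1	72	72			0
tRNA-Thr	H	73	142	70			0
tRNA-Pro	L	143	211	69			-1
tRNA-Phe	H	211	280	70			0
12S rRNA	H	281	1,217	937			0
tRNA-Val	H	1,218	1,287	70			0
16S rRNA	H	1,288	2,880	1,593			0
tRNA-Leu2	H	2,881	2,953	73			0
ND1	H	2,954	3,911	958	GTG	T-	0
tRNA-Ile	H	3,912	3,982	71			0
tRNA-Gln	L	3,983	4,053	71			0
tRNA-Met1	H	4,054	4,122	69			9
tRNA-Met2	H	4,132	4,200	69			0
ND2	H	4,201	5,233	1,033	ATT	T-	0
tRNA-Trp	H	5,234	5,303	70			0
tRNA-Ala	L	5,304	5,373	70			2
tRNA-Asn	L	5,376	5,448	73			0
rep_origin	L	5,449	5,477	29			0
tRNA-Cys	L	5,478	5,542	65			0
tRNA-Tyr	L	5,543	5,609	67			4
COXI	H	5,614	7,164	1,551	ATA	AGG	-9
tRNA-Ser1	L	7,156	7,226	71			0
tRNA-Asp	H	7,227	7,296	70			2
COXII	H	7,299	7,983	685	ATG	T-	0
tRNA-Lys	H	7,984	8,053	70			1
ATP8	H	8,055	8,216	162	ATG	TAA	-7
ATP6	H	8,210	8,891	682	ATG	T-	0
COXIII	H	8,892	9,675	784	ATG	T-	0
tRNA-Gly	H	9,676	9,744	69			0
ND3	H	9,745	10,102	385	GTG	T-	0
tRNA-Arg	H	10,103	10,171	69			1
ND4L	H	10,173	10,457	285	ATG	TAA	-7
ND4	H	10,451	11,813	1,363	ATG	T-	0
tRNA-His	H	11,814	11,813	69			0
tRNA-Ser2	H	11,883	11,950	68			37
ND5	H	11,988	13,811	1824	ATG	TAA	-15
ND6	L	13,797	14,294	498	ATG	AGA	0
tRNA-Glu	L	14,295	14,363	69			7
CYTB	H	14,371	15,516	1,146	ATG	TAG	0
Control region	H	15,517	18,373	2,857			0
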