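Gene	Strand	From	To	Size	Start	Stop	Intergenic
tRNA-Leu1	H	1	81	81			-9
tRNA-Thr	H	73	140	68			0
tRNA-Pro	L	141	209	69			-1
tRNA-Phe	H	209	278	70			0
12S rRNA	H	279	1,212	934			0
tRNA-Val	H	1,213	1,282	70			0
16S rRNA	H	1,283	2,873	1,591			0
tRNA-Leu2	H	2,874	2,946	73			0
ND1	H	2,947	3,904	958	GTG	T-	0
tRNA-Ile	H	3,905	3,975	71			-1
tRNA-Gln	L	3,975	4,045	71			0
tRNA-Met1	H	4,046	4,114	69			9
tRNA-Met2	H	4,124	4,192	69			0
ND2	H	4,193	5,225	1,033	ATT	T-	0
tRNA-Trp	H	5,226	5,295	70			0
tRNA-Ala	L	5,296	5,365	70			2
tRNA-Asn	L	5,368	5,440	73			0
rep_origin	L	5,441	5,470	30			0
tRNA-Cys	L	5,471	5,536	66			0
tRNA-Tyr	L	5,537	5,603	67			4
COXI	H	5,608	7,158	1,551	ATA	AGG	-9
tRNA-Ser1	L	7,150	7,220	71			0
tRNA-Asp	H	7,221	7,289	69			2
COXII	H	7,292	7,976	685	ATG	T-	0
tRNA-Lys	H	7,977	8,046	70			2
ATP8	H	8,049	8,210	162	ATG	TAA	-7
ATP6	H	8,204	8,885	682	ATG	T-	0
COXIII	H	8,886	9,669	784	ATG	T-	0
tRNA-Gly	H	9,670	9,738	69			0
ND3	H	9,739	10,096	358	GTG	T-	0
tRNA-Arg	H	10,097	10,165	69			1
ND4L	H	10,167	10,451	285	ATG	TAA	-7
ND4	H	10,445	11,807	1,363	ATG	T-	0
tRNA-His	H	11,808	11,876	69			0
tRNA-Ser2	H	11,877	11,944	68			44
ND5	H	11,989	13,812	1824	ATG	TAA	-15
ND6	L	13,798	14,295	498	ATG	AGA	0
tRNA-Glu	L	14,296	14,364	69			7
CYTB	H	14,372	15,517	1,146	ATG	TAG	0
Control region	H	15,518	17,660	2,143			0
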