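Gene	Strand	From	To	Size	Start	Stop	Intergenic
tRNA-Leu1	H	1	72	72			-3
tRNA-Thr	H	70	142	73			0
tRNA-Pro	L	143	211	69			-1
tRNA-Phe	H	211	280	70			0
12S rRNA	H	281	1,216	936			0
tRNA-Val	H	1,217	1,286	67			0
16S rRNA	H	1,287	2,873	1,587			0
tRNA-Leu2	H	2,874	2,946	73			0
ND1	H	2,947	3,904	958	GTG	T-	0
tRNA-Ile	H	3,905	3,975	71			0
tRNA-Gln	L	3,976	4,046	71			0
tRNA-Met1	H	4,047	4,115	69			10
tRNA-Met2	H	4,126	4,194	69			0
ND2	H	4,195	5,227	1,033	ATT	T-	0
tRNA-Trp	H	5,228	5,297	70			0
tRNA-Ala	L	5,298	5,367	70			2
tRNA-Asn	L	5,370	5,442	73			0
rep_origin	L	5,443	5,471	29			0
tRNA-Cys	L	5,472	5,536	65			0
tRNA-Tyr	L	5,537	5,603	67			4
COXI	H	5,608	7,158	1,551	ATA	AGG	-9
tRNA-Ser1	L	7,150	7,220	71			0
tRNA-Asp	H	7,221	7,289	69			1
COXII	H	7,291	7,975	685	ATG	T-	0
tRNA-Lys	H	7,976	8,045	70			3
ATP8	H	8,049	8,210	162	ATG	TAA	-7
ATP6	H	8,204	8,885	682	ATG	T-	0
COXIII	H	8,886	9,669	784	ATG	T-	0
tRNA-Gly	H	9,670	9,738	69			0
ND3	H	9,739	10,096	358	GTG	T-	0
tRNA-Arg	H	10,097	10,165	69			1
ND4L	H	10,167	10,451	285	ATG	TAA	-7
ND4	H	10,445	11,807	1,363	ATG	T-	0
tRNA-His	H	11,808	11,875	68			0
tRNA-Ser2	H	11,876	11,943	68			106
ND5	H	12,050	13,873	1824	ATG	TAA	-15
ND6	L	13,859	14,356	498	ATG	AGA	0
tRNA-Glu	L	14,357	14,425	69			7
CYTB	H	14,433	15,578	1,146	ATG	TAG	0
Control region	H	15,579	17,837	2,259			1
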