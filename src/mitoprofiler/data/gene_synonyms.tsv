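alias	canonical
COI	COX1
COXI	COX1
CO1	COX1
COX1	COX1
MT-CO1	COX1
cytochrome c oxidase subunit I	COX1
cytochrome c oxidase subunit 1	COX1
COII	COX2
COXII	COX2
CO2	COX2
COX2	COX2
cytochrome c oxidase subunit II	COX2
cytochrome c oxidase subunit 2	COX2
COIII	COX3
COXIII	COX3
CO3	COX3
COX3	COX3
cytochrome c oxidase subunit III	COX3
cytochrome c oxidase subunit 3	COX3
ND1	ND1
NAD1	ND1
NADH1	ND1
NADH dehydrogenase subunit 1	ND1
ND2	ND2
NAD2	ND2
NADH dehydrogenase subunit 2	ND2
ND3	ND3
NAD3	ND3
NADH dehydrogenase subunit 3	ND3
ND4	ND4
NAD4	ND4
NADH dehydrogenase subunit 4	ND4
ND4L	ND4L
NAD4L	ND4L
NADH dehydrogenase subunit 4L	ND4L
ND5	ND5
NAD5	ND5
NADH dehydrogenase subunit 5	ND5
ND6	ND6
NAD6	ND6
NADH dehydrogenase subunit 6	ND6
ATP6	ATP6
ATPASE6	ATP6
ATP synthase F0 subunit 6	ATP6
ATP8	ATP8
ATPASE8	ATP8
ATP synthase F0 subunit 8	ATP8
CYTB	CYTB
CYT B	CYTB
COB	CYTB
CB	CYTB
cytochrome b	CYTB
12S RRNA	12S-rRNA
12S RNA	12S-rRNA
12S	12S-rRNA
RRNS	12S-rRNA
S-RRNA	12S-rRNA
12S ribosomal RNA	12S-rRNA
small subunit ribosomal RNA	12S-rRNA
16S RRNA	16S-rRNA
16S RNA	16S-rRNA
16S	16S-rRNA
RRNL	16S-rRNA
L-RRNA	16S-rRNA
16S ribosomal RNA	16S-rRNA
large subunit ribosomal RNA	16S-rRNA
TRNA-PHE	tRNA-Phe
TRNF	tRNA-Phe
TRNA-VAL	tRNA-Val
TRNV	tRNA-Val
TRNA-LEU1	tRNA-Leu1
TRNA-LEU(UUR)	tRNA-Leu2
TRNA-LEU(CUN)	tRNA-Leu1
TRNL1	tRNA-Leu1
TRNA-LEU2	tRNA-Leu2
TRNL2	tRNA-Leu2
TRNA-ILE	tRNA-Ile
TRNI	tRNA-Ile
TRNA-GLN	tRNA-Gln
TRNQ	tRNA-Gln
TRNA-MET	tRNA-Met1
TRNA-MET1	tRNA-Met1
TRNA-MET2	tRNA-Met2
TRNM	tRNA-Met1
TRNA-TRP	tRNA-Trp
TRNW	tRNA-Trp
TRNA-ALA	tRNA-Ala
TRNA	tRNA-Ala
TRNA-ASN	tRNA-Asn
TRNN	tRNA-Asn
TRNA-CYS	tRNA-Cys
TRNC	tRNA-Cys
TRNA-TYR	tRNA-Tyr
TRNY	tRNA-Tyr
TRNA-SER1	tRNA-Ser1
TRNA-SER(UCN)	tRNA-Ser1
TRNS1	tRNA-Ser1
TRNA-SER2	tRNA-Ser2
TRNA-SER(AGY)	tRNA-Ser2
TRNS2	tRNA-Ser2
TRNA-ASP	tRNA-Asp
TRND	tRNA-Asp
TRNA-LYS	tRNA-Lys
TRNK	tRNA-Lys
TRNA-GLY	tRNA-Gly
TRNG	tRNA-Gly
TRNA-ARG	tRNA-Arg
TRNR	tRNA-Arg
TRNA-HIS	tRNA-His
TRNH	tRNA-His
TRNA-GLU	tRNA-Glu
TRNE	tRNA-Glu
TRNA-THR	tRNA-Thr
TRNT	tRNA-Thr
TRNA-PRO	tRNA-Pro
TRNP	tRNA-Pro
REP_ORIGIN	OL
OL	OL
O_L	OL
L-STRAND	OL
L-strand origin	OL
origin of L-strand replication	OL
CONTROL REGION	CR
D-LOOP	CR
D-loop	CR
CR	CR
putative control region	CR
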