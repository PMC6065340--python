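# Default control-region motif set. TAS is the 17-bp anuran termination-associated
# sequence consensus; the CSB-1/2/3 and OH entries are synthetic placeholder
# consensus strings (the conserved-sequence-block alignments are not distributed in
# machine-readable form), sized to the published feature lengths (28/19/18/72 bp)
# and shared with the synthetic-genome generator. Edit or replace via --motifs.
name	consensus	max_mismatches
TAS	TATAAGACATCTATGTA	2
CSB-1	TTAATGTAGTAAGAGACCACCAACGGTT	4
CSB-2	CAAACCCCCCCTCCCCCGC	3
CSB-3	TGCCAAACCCCAAAAACA	3
OH	CACCACTAACACCCAAAGCTGGTATTCTAATTAAACTACTTCCCTGATCAACAACCAAAACTTTCATCGTAC	8
GACAT	GACAT	0
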