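library	mirna_id	arm	seed	sequence	reference_is_most_abundant	count
cells	hsa-miR-21-5p	5p	AGCTTA	TAGCTTATCAGACTGATGTTGA	True	382634
cells	hsa-let-7f-5p	5p	GAGGTA	TGAGGTAGTAGATTGTATAGTT	True	243882
cells	hsa-let-7b-5p	5p	GAGGTA	TGAGGTAGTAGGTTGTGTGGTT	True	91479
cells	hsa-miR-100-5p	5p	ACCCGT	AACCCGTAGATCCGAACTTGTG	True	82325
cells	hsa-let-7a-5p	5p	GAGGTA	TGAGGTAGTAGGTTGTATAGTT	True	66589
cells	hsa-miR-125b-5p	5p	CCCTGA	TCCCTGAGACCCTAACTTGTGA	True	41096
cells	hsa-let-7i-5p	5p	GAGGTA	TGAGGTAGTAGTTTGTGCTGTT	True	30233
cells	hsa-let-7g-5p	5p	GAGGTA	TGAGGTAGTAGTTTGTACAGTT	True	28900
cells	hsa-miR-148a-3p	3p	CAGTGC	TCAGTGCACTACAGAACTTTGT	True	26923
cells	hsa-miR-24-3p	3p	GGCTCA	TGGCTCAGTTCAGCAGGAACAG	True	26085
cells	hsa-miR-19b-3p	3p	GTGCAA	TGTGCAAATCCATGCAAAACTGA	True	23649
cells	hsa-let-7c	5p	GAGGTA	TGAGGTAGTAGGTTGTATGGTT	True	21557
cells	hsa-miR-25-3p	3p	ATTGCA	CATTGCACTTGTCTCGGTCTGA	True	17757
cells	hsa-miR-182-5p	5p	TTGGCA	TTTGGCAATGGTAGAACTCACACT	True	15213
cells	hsa-miR-425-5p	5p	ATGACA	AATGACACGATCACTCCCGTTGA	False	12236
cells	hsa-miR-26a-5p	5p	TCAAGT	TTCAAGTAATCCAGGATAGGCT	True	11993
cells	hsa-miR-181a-5p	5p	ACATTC	AACATTCAACGCTGTCGGTGAGT	True	11329
cells	hsa-miR-99a-5p	5p	ACCCGT	AACCCGTAGATCCGATCTTGTG	True	10476
cells	hsa-miR-103a-3p	3p	GCAGCA	AGCAGCATTGTACAGGGCTATGA	True	10305
exosomes	hsa-let-7f-5p	5p	GAGGTA	TGAGGTAGTAGATTGTATAGTT	True	95
exosomes	hsa-let-7a-5p	5p	GAGGTA	TGAGGTAGTAGGTTGTATAGTT	True	57
exosomes	hsa-miR-21-5p	5p	AGCTTA	TAGCTTATCAGACTGATGTTGA	True	38
exosomes	hsa-miR-26a-5p	5p	TCAAGT	TTCAAGTAATCCAGGATAGGCT	True	29
exosomes	hsa-miR-27b-3p	3p	TCACAG	TTCACAGTGGCTAAGTTCTGC	True	26
exosomes	hsa-let-7b-5p	5p	GAGGTA	TGAGGTAGTAGGTTGTGTGGTT	True	22
exosomes	hsa-miR-19a-3p	3p	GTGCAA	TGTGCAAATCTATGCAAAACTGA	True	21
exosomes	hsa-miR-100-5p	5p	ACCCGT	AACCCGTAGATCCGAACTTGTG	True	18
exosomes	hsa-miR-148a-3p	3p	CAGTGC	TCAGTGCACTACAGAACTTTGT	True	12
exosomes	hsa-let-7i-5p	5p	GAGGTA	TGAGGTAGTAGTTTGTGCTGTT	True	11
exosomes	hsa-miR-19b-3p	3p	GTGCAA	TGTGCAAATCCATGCAAAACTGA	True	11
exosomes	hsa-miR-25-3p	3p	ATTGCA	CATTGCACTTGTCTCGGTCTGA	True	11
exosomes	hsa-miR-320a	3p	AAAGCT	AAAAGCTGGGTTGAGAGGGCGA	True	11
exosomes	hsa-miR-423-5p	5p	GAGGGG	TGAGGGGCAGAGAGCGAGACTTT	True	10
exosomes	hsa-let-7g-5p	5p	GAGGTA	TGAGGTAGTAGTTTGTACAGTT	True	9
exosomes	hsa-miR-92a-3p	3p	ATTGCA	TATTGCACTTGTCCCGGCCTGT	True	9
exosomes	hsa-let-7c	5p	GAGGTA	TGAGGTAGTAGGTTGTATGGTT	True	7
exosomes	hsa-miR-125b-5p	5p	CCCTGA	TCCCTGAGACCCTAACTTGTGA	True	6
exosomes	hsa-miR-181a-5p	5p	ACATTC	AACATTCAACGCTGTCGGTGAGT	True	6
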