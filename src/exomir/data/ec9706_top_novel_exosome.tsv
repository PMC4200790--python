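candidate_id	arm	seed	most_abundant_sequence	reference_is_most_abundant	cells_count	exosomes_count
hsa-miR-chr12_3064	3p	GAGAGG	GGAGAGGTGGATGAGTGGTTTA	False	0	339
hsa-miR-chr1_9487	3p	GAGAGG	GGAGAGGTGGATGAGTGGTTTA	False	0	339
hsa-miR-chr15_4885	3p	TTCAAG	GTTCAAGTCCAGCTGGG	True	30	306
hsa-miR-chr3_14243	3p	TTCAAG	GTTCAAGTCCAGCTGGG	True	30	306
hsa-miR-chr18_7463	3p	ACGTGA	CACGTGAAACCCTGTCTGAAT	False	14	137
hsa-miR-chr2_11998	5p	AGGACT	AAGGCAGGACTGGTGACTGGGGTG	False	7	59
hsa-miR-chrY_24624	3p	TCCCTG	GTGTCCCTGGTTCGAGCCC	False	0	55
hsa-miR-chr6_18451	3p	GTCGTG	GGTCGTGGGTTCGAGC	False	0	37
hsa-miR-chr20_11216	3p	GTTCGA	GGTTCAAATCCTGTCTTCT	False	2	28
hsa-miR-chr1_9933	5p	TCTTTG	ATCTCTTTGAGTTCTCACCA	False	2	19
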