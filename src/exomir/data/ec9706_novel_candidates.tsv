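candidate_id	precursor_coordinate	consensus_mature_sequence	length	arm	cells_count	exosomes_count	multi_locus
hsa-miR-chr18_7463	chr18:42911426..42911487: +	CACGTGAAACCCTGTCT	17	3p	14	137	False
hsa-miR-chr2_11998	chr2:9376082..9376166: +	CAGGACTGGGGACTGGGGTG	20	5p	7	59	False
hsa-miR-chr20_11216	chr20:39392006..39392060: -	GGTTCGAATCCTGTCTTCT	19	3p	2	28	False
hsa-miR-chr1_9933	chr1:45874140..45874224: -	CTCTTTGAGTTCTCACCA	18	5p	2	19	False
hsa-miR-chr5_17564	chr5:33712846..33712885: -	GTACTCAAGAGGCTGAAGA	19	5p	7	18	False
hsa-miR-chr1_8755	chr1:62567393..62567462: +	TCAAATCCTGTCTGACC	17	3p	2	17	False
hsa-miR-chr7_20613	chr7:25989517..25989563: -	TCAGTGCACTACAGAACTTTGT	22	5p	26923	12	False
hsa-miR-chr11_1761	chr11:31858407..31858458: -	GCATGGGTGGTTCAGTGGTAGAATT	25	5p	202	5	False
hsa-miR-chr19_8205	chr19:13947044..13947124: -	TGGCTCAGTTCAGCAGGAACAG	22	5p	26085	4	False
hsa-miR-chr16_5626	chr16:14397874..14397964: +	AACTGGCCCTCAAAGTCCCGCT	22	5p	5460	2	False
hsa-miR-chr15_4885	chr15:43193729..43193791: +	GTTCAAGTCCAGCTGGG	17	3p	30	306	True
hsa-miR-chr3_14243	chr3:101824879..101824941: +	GTTCAAGTCCAGCTGGG	17	3p	30	306	True
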