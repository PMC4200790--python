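library	class	unique_count	total_count
cells	mRNA	59655	92372
cells	repeat	31421	106725
cells	miRNA	56421	3163192
cells	rRNA	260307	1423180
cells	tRNA	80635	856084
cells	snRNA	27935	297457
cells	unannotated	1403502	3647636
exosomes	mRNA	5988	21742
exosomes	repeat	5066	14454
exosomes	miRNA	7726	94141
exosomes	rRNA	85303	542830
exosomes	tRNA	119500	2325394
exosomes	snRNA	1823	5472
exosomes	unannotated	1001224	4188375
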