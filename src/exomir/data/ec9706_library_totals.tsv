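library	clean_reads	trimmed_reads	unique_tags
cells	13088424	9595761	1919950
exosomes	7736476	7193132	1226905
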