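metric	value
known_mirnas_cells	342
known_mirnas_exosomes	48
known_mirnas_shared	48
novel_mirnas_cells	64
novel_mirnas_exosomes	32
novel_mirnas_shared	12
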