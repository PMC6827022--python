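name	recognition	cut_offset
BspHI	TCATGA	1
EcoRI	GAATTC	1
HindIII	AAGCTT	1
BamHI	GGATCC	1
NdeI	CATATG	2
DraI	TTTAAA	3
HpaI	GTTAAC	3
SspI	AATATT	3
PstI	CTGCAG	5
KpnI	GGTACC	5
AvaII	GGWCC	1
TaqI	TCGA	1
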