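attribute_code	conformation	protein_id
DNMT	heterochromatic	DNMT1
DNMT	heterochromatic	DNMT3A
DNMT	heterochromatic	DNMT3B
HAT	euchromatic	KAT2A
HAT	euchromatic	KAT2B
HAT	euchromatic	EP300
HAT	euchromatic	CREBBP
HDAC	heterochromatic	HDAC1
HDAC	heterochromatic	HDAC2
HDAC	heterochromatic	HDAC3
HDAC	heterochromatic	SIRT1
H3K4	euchromatic	KMT2A
H3K4	euchromatic	KMT2D
H3K4	euchromatic	SETD1A
H3K36	euchromatic	SETD2
H3K36	euchromatic	NSD1
H3K79	euchromatic	DOT1L
H3R17	euchromatic	CARM1
H3K9	heterochromatic	SUV39H1
H3K9	heterochromatic	EHMT2
H3K9	heterochromatic	SETDB1
H3K27	heterochromatic	EZH2
H3K27	heterochromatic	EZH1
H4K20	heterochromatic	KMT5A
H4K20	heterochromatic	KMT5B
H3K4i	heterochromatic	KDM1A
H3K4i	heterochromatic	KDM5A
H3K4i	heterochromatic	KDM5B
H3K36i	heterochromatic	KDM2A
H3K36i	heterochromatic	KDM4A
H3R2i	heterochromatic	JMJD6
H4R3i	heterochromatic	JMJD6
H3K27i	euchromatic	KDM6A
H3K27i	euchromatic	KDM6B
H3S10	euchromatic	RPS6KA5
H3S10	euchromatic	RPS6KA4
H3S10	euchromatic	CHUK
H3S10i	heterochromatic	DUSP1
ATP	ambivalent	SMARCA4
ATP	ambivalent	SMARCA2
ATP	ambivalent	CHD1
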