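gene	chrom	pos	ref	alt	cdna	protein
CTNNB1	chr3	41266137	C	T	c.134C>T	S45F
KRAS	chr12	25398284	C	T	c.35G>A	G12D
PIK3CA	chr3	178952085	A	G	c.3140A>G	H1047R
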