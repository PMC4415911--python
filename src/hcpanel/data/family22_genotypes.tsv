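Family	Individual	Variant	Status
22	P	BRCA1:c.2110_2111delAA	carrier
22	M	BRCA1:c.2110_2111delAA	carrier
22	A1	BRCA1:c.2110_2111delAA	carrier
22	A2	BRCA1:c.2110_2111delAA	carrier
22	GF	BRCA1:c.2110_2111delAA	carrier
22	S	BRCA1:c.2110_2111delAA	non_carrier
22	P	MSH3:c.162_179del18	carrier
22	M	MSH3:c.162_179del18	carrier
22	A1	MSH3:c.162_179del18	carrier
22	A2	MSH3:c.162_179del18	non_carrier
22	GF	MSH3:c.162_179del18	carrier
22	S	MSH3:c.162_179del18	carrier
22	P	MUTYH:c.850-2A>G	carrier
22	S	MUTYH:c.850-2A>G	non_carrier
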