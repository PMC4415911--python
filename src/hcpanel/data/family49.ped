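# Synthetic reconstruction of study family 49 (single MSH3 variant,
# Lynch-syndrome-like maternal lineage of colorectal tumours).
# Columns: Family Individual Father Mother Sex Phenotype CancerTypes AgeDx Proband
49	GF	0	0	1	1	0	0	0
49	GM	0	0	2	2	colon	60	0
49	F	0	0	1	1	0	0	0
49	M	GF	GM	2	2	breast;colon	55,58	0
49	U	GF	GM	1	2	rectum	50	0
49	A	GF	GM	2	2	colon	47	0
49	P	F	M	2	2	breast	32	1
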