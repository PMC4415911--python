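# Synthetic reconstruction of study family 22 (proband carries BRCA1,
# MSH3 and MUTYH candidate variants; maternal breast-cancer lineage).
# Columns: Family Individual Father Mother Sex Phenotype CancerTypes AgeDx Proband
22	GF	0	0	1	2	breast	68	0
22	GM	0	0	2	1	0	0	0
22	F	0	0	1	1	0	0	0
22	M	GF	GM	2	2	breast;lymphoma	60,61	0
22	A1	GF	GM	2	2	breast	49	0
22	A2	GF	GM	2	2	breast	34	0
22	A3	GF	GM	2	2	breast	50	0
22	P	F	M	2	2	breast	37	1
22	S	F	M	2	1	0	0	0
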