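Gene	cDNA	Evidence	Source
BRCA1	c.2110_2111delAA	database	BIC
BRCA1	c.5503C>T	database	BIC
BRCA1	c.5468-1_5474del8	literature	prior cohort report
BRCA2	c.2442delC	literature	prior cohort reports
BRCA2	c.2808_2811delACAA	database	BIC
BRCA2	c.5682C>G	database	BIC
BRCA2	c.7007G>A	database	BIC
BRCA2	c.7409dupT	literature	prior cohort report
BRCA2	c.8485C>T	database	BIC
TP53	c.523C>G	database	p53 mutation database
TP53	c.839G>C	database	p53 mutation database
MLH1	c.194G>A	literature	published functional report
MSH3	c.199_207del9	database	rs3045983
CDH1	c.1296C>G	literature	published gastric-cancer report
PALB2	c.1050_1051delinsTCT	literature	published report
SLX4	c.3583_3585delATT	database	rs199897550
MUTYH	c.850-2A>G	literature	published splice-variant report
WRN	c.4245dupT	literature	heterozygote breast-cancer risk report
CYP17A1	c.987delC	literature	heterozygote early-onset risk report
SPINK1	c.194+2T>C	literature	published splice-variant report
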