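Sample	Gene	Transcript	cDNA	Protein	Chrom	Start	End	Region	MAF_1000G	SIFT	PolyPhen2	PhyloP	LRT	Genotype	Qual	NeighborDist	Depth
56	BRCA1	NM_007294	c.754delC	p.R252Vfs*46	17	41246794	41246794	exonic	0	-	-	-	-	het	99	10	50
6	BRCA1	NM_007294	c.1214C>G	p.S405*	17	41246334	41246334	exonic	0	-	-	-	-	het	99	10	50
22	BRCA1	NM_007294	c.2110_2111delAA	p.N704Cfs*7	17	41245438	41245439	exonic	0	-	-	-	-	het	99	10	50
5	BRCA1	NM_007294	c.4228delG	p.E1410Kfs*5	17	41234551	41234551	exonic	0	-	-	-	-	het	99	10	50
29	BRCA1	NM_007294	c.5503C>T	p.R1835*	17	41197784	41197784	exonic	0	-	-	-	-	het	99	10	50
26	BRCA1	NM_007294	c.5468-1_5474del8	p.A1823Gfs*9	17	41197813	41197820	splicing	0	-	-	-	-	het	99	10	50
52	BRCA1	NM_007294	c.5468-1_5474del8	p.A1823Gfs*9	17	41197813	41197820	splicing	0	-	-	-	-	het	99	10	50
3	BRCA2	NM_000059	c.2442delC	p.M815Wfs*10	13	32910934	32910934	exonic	0	-	-	-	-	het	99	10	50
4	BRCA2	NM_000059	c.2442delC	p.M815Wfs*10	13	32910934	32910934	exonic	0	-	-	-	-	het	99	10	50
68	BRCA2	NM_000059	c.2808_2811delACAA	p.A938Pfs*21	13	32911300	32911303	exonic	0	-	-	-	-	het	99	10	50
2	BRCA2	NM_000059	c.5682C>G	p.Y1894*	13	32914174	32914174	exonic	0	-	-	-	-	het	99	10	50
7	BRCA2	NM_000059	c.5699C>G	p.S1900*	13	32914191	32914191	exonic	0	D	B	C	NC	het	99	10	50
54	BRCA2	NM_000059	c.7007G>A	p.R2336H	13	32921033	32921033	exonic	0	D	B	C	NC	het	99	10	50
24	BRCA2	NM_000059	c.7142delC	p.P2381Hfs*13	13	32929132	32929132	exonic	0	-	-	-	-	het	99	10	50
45	BRCA2	NM_000059	c.7409dupT	p.T2471Hfs*4	13	32929399	32929399	exonic	0	-	-	-	-	het	99	10	50
42	BRCA2	NM_000059	c.8485C>T	p.Q2829*	13	32944692	32944692	exonic	0	-	-	-	-	het	99	10	50
13	BRCA2	NM_000059	c.8517C>A	p.Y2839*	13	32945122	32945122	exonic	0	D	B	C	C	het	99	10	50
71	BRCA2	NM_000059	c.8956_8957insAA	p.I2986Kfs*3	13	32953889	32953889	exonic	0	-	-	-	-	het	99	10	50
65	TP53	NM_000546	c.320dupA	p.Y107*	17	7579367	7579367	exonic	0	-	-	-	-	het	99	10	50
83	TP53	NM_000546	c.523C>G	p.R175G	17	7578407	7578407	exonic	0	D	PD	C	C	het	99	10	50
38	TP53	NM_000546	c.839G>C	p.R280T	17	7577099	7577099	exonic	0	D	PD	C	C	het	99	10	50
46	MLH1	NM_000249	c.194G>A	p.G65D	3	37038187	37038187	exonic	0	D	PD	C	C	het	99	10	50
67	MLH3	NM_014381	c.1189_1191delTAT	p.I397del	14	75515169	75515171	exonic	0	-	-	-	-	het	99	10	50
22	MSH3	NM_002439	c.162_179del18	p.A57_A62del	5	79950708	79950725	exonic	0	-	-	-	-	het	99	10	50
49	MSH3	NM_002439	c.199_207del9	p.P67_P69del	5	79950745	79950753	exonic	0	-	-	-	-	het	99	10	50
75	MSH3	NM_002439	c.2305delG	p.V769*	5	80071564	80071564	exonic	0	-	-	-	-	het	99	10	50
94	CDH1	NM_004360	c.1296C>G	p.N432K	16	68847374	68847374	exonic	0	D	PD	NC	C	het	99	10	50
86	RAD51C	NM_058216	c.343dupG	p.V115Gfs*24	17	56772489	56772489	exonic	0	-	-	-	-	het	99	10	50
51	PALB2	NM_024675	c.1050_1051delinsTCT	p.Q350Hfs*11	16	23646815	23646815	exonic	0	-	-	-	-	het	99	10	50
77	RAD50	NM_005732	c.1291_1295delGAGAT	p.E431Kfs*3	5	131925368	131925372	exonic	0	-	-	-	-	het	99	10	50
35	FANCI	NM_001113378	c.2699_2704dupGGCAAT	p.Q901_F902insWQ	15	89843611	89843611	exonic	0	-	-	-	-	het	99	10	50
86	SLX4	NM_032444	c.3583_3585delATT	p.I1195del	16	3640054	3640056	exonic	0	-	-	-	-	het	99	10	50
7	FANCD2	NM_033084	c.4234_4239delAGTGAG	p.S1412_E1413del	3	10140452	10140457	exonic	0	-	-	-	-	het	99	10	50
77	CDKN2A	NM_000077	c.480G>A	p.W160*	9	21968748	21968748	exonic	0	-	-	-	-	het	99	10	50
64	CYP17A1	NM_000102	c.987delC	p.Y329*	10	104592420	104592420	exonic	0	-	-	-	-	het	99	10	50
88	FGFR3	NM_000142	c.2072delG	p.G691Afs*17	4	1808976	1808976	exonic	0	-	-	-	-	het	99	10	50
75	RGSL1	NM_001137669	c.1357C>T	p.Q453*	1	182443603	182443603	exonic	0	-	-	-	-	het	99	10	50
22	MUTYH	NM_001128425	c.850-2A>G	p.?	1	45797760	45797760	splicing	0.002	-	-	-	-	het	99	10	50
96	SPINK1	NM_003122	c.194+2T>C	p.?	5	147207583	147207583	splicing	0.001	-	-	-	-	het	99	10	50
60	TNFRSF13B	NM_012452	c.704_705delCT	p.P235Rfs*169	17	16855857	16855857	exonic	0	-	-	-	-	het	99	10	50
29	TNFRSF13B	NM_012452	c.102delC	p.E36Kfs*48	17	16843038	16843039	exonic	0	-	-	-	-	het	99	10	50
24	WRN	NM_000553	c.4245dupT	p.D1416*	8	31030564	31030564	exonic	0	-	-	-	-	het	99	10	50
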