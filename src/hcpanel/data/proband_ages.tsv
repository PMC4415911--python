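Sample	AgeDx
2	37
3	46
4	42
5	40
6	32
7	30
13	32
22	37
24	26,36
26	40
29	39
35	30
38	37
42	34
45	43
46	52
49	32
51	45
52	34
54	70
56	35
60	47
64	27
65	30
67	46
68	38
71	28
75	51
77	34
83	20
86	52
88	45
94	47
96	35
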