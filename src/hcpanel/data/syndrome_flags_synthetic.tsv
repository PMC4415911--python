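Family	HBOCS	LFS	LS
1	1	1	0
2	1	0	0
3	1	0	0
4	1	0	1
5	1	0	0
6	1	0	0
7	1	0	0
8	1	1	0
9	1	1	0
10	1	1	0
11	1	1	0
12	1	1	0
13	1	0	0
14	1	1	0
15	1	1	0
16	1	1	0
17	1	0	1
18	1	0	1
19	1	0	1
20	1	0	1
21	1	0	1
22	1	0	0
23	1	0	1
24	1	0	1
25	1	0	1
26	1	0	0
27	1	0	1
28	1	0	0
29	1	0	0
30	1	0	0
31	1	0	0
32	1	0	0
33	1	0	0
34	1	0	0
35	1	0	0
36	1	0	0
37	1	0	0
38	1	0	0
39	1	0	0
40	1	0	0
41	1	0	0
42	1	0	1
43	1	0	0
44	1	0	0
45	1	0	0
46	1	0	1
47	1	0	0
48	1	0	0
49	1	1	1
50	1	0	0
51	1	0	0
52	1	0	0
53	1	0	0
54	1	0	0
55	1	0	0
56	1	0	0
57	1	0	0
58	1	0	0
59	1	0	0
60	1	0	1
61	1	0	0
62	1	0	0
63	1	0	0
64	1	0	0
65	1	1	1
66	1	0	0
67	1	0	0
68	1	0	0
69	1	0	0
70	1	0	0
71	1	0	0
72	1	0	0
73	1	0	0
74	1	0	0
75	1	0	0
76	1	0	0
77	1	0	0
78	1	0	0
79	1	0	0
80	1	0	0
81	1	0	0
82	1	0	0
83	1	0	0
84	1	0	0
85	0	0	0
86	1	0	0
87	0	0	0
88	1	0	0
89	0	0	0
90	0	0	0
91	0	0	0
92	0	0	0
93	0	0	0
94	1	0	0
95	0	0	0
96	1	0	0
97	0	0	0
98	0	0	0
99	0	0	0
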