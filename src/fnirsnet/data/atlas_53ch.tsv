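channel	hemisphere	roi
1	left	DLPFC
2	left	DLPFC
3	left	DLPFC
4	left	DLPFC
5	left	DLPFC
6	left	FEF
7	left	FEF
8	left	FEF
9	left	FEF
10	left	FEF
11	left	PreM_SMA
12	left	PreM_SMA
13	left	PreM_SMA
14	left	PreM_SMA
15	left	PreM_SMA
16	left	BROCA
17	left	BROCA
18	left	BROCA
19	left	BROCA
20	left	BROCA
21	left	FPA
22	left	FPA
23	left	FPA
24	left	FPA
26	left	FPA
25	midline	FPA
28	midline	FPA
29	midline	FPA
27	right	FPA
30	right	FPA
31	right	FPA
32	right	FPA
33	right	FPA
34	right	BROCA
35	right	BROCA
36	right	BROCA
37	right	BROCA
38	right	BROCA
39	right	PreM_SMA
40	right	PreM_SMA
41	right	PreM_SMA
42	right	PreM_SMA
43	right	PreM_SMA
44	right	FEF
45	right	FEF
46	right	FEF
47	right	FEF
48	right	FEF
49	right	DLPFC
50	right	DLPFC
51	right	DLPFC
52	right	DLPFC
53	right	DLPFC
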