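position	mutant_allele	wildtype_allele	lod_smrt	lod_ultraseek	lod_dpcr
153	G	A	0.1	na	na
195	C	T	0.1	na	na
1719	A	G	0.1	na	na
2706	G	A	0.1	na	na
6221	C	T	1.0	1.0	na
6371	T	C	1.0	0.1	na
6776	T	C	0.1	na	na
7028	T	C	0.1	na	na
8506	C	T	0.1	1.0	na
9966	G	A	0.1	na	na
11719	A	G	0.1	na	na
12084	T	C	0.1	0.1	na
12705	T	C	0.1	na	na
13966	G	A	0.1	0.1	0.01
14470	C	T	0.1	0.1	na
14766	T	C	0.1	na	na
15310	C	T	0.1	0.1	0.1
15380	A	G	0.1	na	na
16093	C	T	0.1	na	na
16184	C	T	0.1	na	na
16223	T	C	0.1	na	na
16265	G	A	0.1	na	na
16278	T	C	0.1	na	na
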