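SNP	Chr	Position	EAF	EA	OA	Beta	SE	p
rs12614	6	31946402	0.92	C	T	0.637	0.053	1.28e-34
rs422951	6	32220606	0.81	T	C	0.239	0.030	5.33e-16
rs378352	6	33007157	0.39	A	G	0.231	0.022	1.04e-23
rs1883832	20	46118343	0.37	T	C	0.174	0.023	2.95e-15
rs3130542	6	31264334	0.16	A	G	0.157	0.031	8.66e-7
rs652888	6	31883457	0.24	G	A	0.131	0.024	9.92e-7
rs2856718	6	32702478	0.55	T	C	0.247	0.022	7.35e-28
rs7453920	6	32762235	0.88	G	A	0.693	0.045	1.28e-60
rs3077	6	33065245	0.66	G	A	0.371	0.023	1.15e-53
rs9277535	6	33087084	0.58	G	A	0.419	0.024	9.84e-71
rs2853953	6	31267728	0.90	G	A	0.385	0.042	5.06e-20
rs1419881	6	31162816	0.55	A	G	0.113	0.023	2.88e-7
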