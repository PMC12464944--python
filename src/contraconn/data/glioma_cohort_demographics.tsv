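subject	sex	diagnosis	idh	who_grade	age	lesion_volume	n_runs
1	M	Glioblastoma	wildtype	high	73	11349	1
2	M	Glioblastoma	wildtype	high	69	31102	1
3	F	Glioblastoma	mutant	high	58	188060	1
4	M	Glioblastoma	wildtype	high	57	145300	2
5	M	Oligodendroglioma	mutant	low	46	67034	2
6	F	Glioblastoma	mutant	high	45	277109	2
7	M	Anaplastic astrocytoma	wildtype	high	42	44270	2
8	M	Oligodendroglioma	mutant	high	67	42216	2
9	M	Glioblastoma	wildtype	high	67	18604	2
10	M	Glioblastoma	mutant	high	28	193209	1
11	F	Anaplastic astrocytoma	mutant	high	36	64557	2
12	F	Glioblastoma	wildtype	high	49	11801	1
13	F	Gemistocytic astrocytoma	mutant	low	55	15297	2
14	M	Diffuse astrocytoma	mutant	low	20	7570	2
15	M	Diffuse astrocytoma	mutant	low	23	19704	2
16	M	Oligodendroglioma	mutant	low	57	9308	2
17	M	Oligodendroglioma	mutant	low	32	19057	2
18	F	Anaplastic astrocytoma	mutant	high	29	69361	2
19	F	Glioblastoma	wildtype	high	75	60841	2
20	M	Glioblastoma	wildtype	high	56	45310	1
21	M	Anaplastic astrocytoma	mutant	high	28	62731	1
22	M	Anaplastic astrocytoma	wildtype	high	70	102302	1
23	F	Glioblastoma	wildtype	high	66	6054	1
24	M	Glioblastoma	wildtype	high	67	199912	1
25	F	Glioblastoma	wildtype	high	52	28292	1
26	F	Oligodendroglioma	mutant	low	60	17316	2
27	M	Astrocytoma	wildtype	low	25	74908	2
28	M	Anaplastic oligodendroglioma	mutant	high	31	66304	2
29	F	Angiocentric glioma	wildtype	low	24	8505	2
30	M	Glioblastoma	wildtype	high	59	116479	2
31	F	Oligodendroglioma	mutant	low	62	25170	2
32	M	Diffuse astrocytoma	mutant	low	45	110326	2
33	M	Astrocytoma	wildtype	low	70	19704	2
34	M	Glioblastoma	wildtype	high	48	129643	1
35	F	Oligodendroglioma	mutant	low	40	12465	1
36	M	Glioblastoma	wildtype	high	42	192798	1
37	M	Glioblastoma	wildtype	high	76	1538	2
38	M	Anaplastic oligodendroglioma	mutant	high	28	37022	2
39	F	Glioblastoma	wildtype	high	79	35746	2
40	M	Infiltrating astrocytoma	mutant	low	41	33495	2
41	M	Glioblastoma	wildtype	high	63	16919	2
42	F	Oligodendroglioma	mutant	low	53	64556	2
43	F	Infiltrating glioma	mutant	low	43	23096	1
44	M	Anaplastic astrocytoma	mutant	high	35	47252	2
45	F	Anaplastic astrocytoma	mutant	high	40	26814	2
46	M	Glioblastoma	wildtype	high	62	83984	2
47	M	Glioblastoma	wildtype	high	75	96475	2
48	M	Anaplastic glioma	mutant	high	34	71566	2
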