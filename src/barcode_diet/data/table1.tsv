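sample_no	sample_id	total_length_mm	body_length_mm	weight_g	date	pcr_status	n_pcr_attempts	n_clones
1	B-3	31	24	0.3	2012-06-13	success	1	10
2	A-7-1	32	25	0.3	2012-06-13	success	1	10
3	B-5	34	28	0.4	2012-06-13	success	1	8
4	B-7	35	27	0.4	2012-06-13	success	1	10
5	A-7-3	36	30	0.3	2012-06-13	success	1	10
6	B-4	36	29	0.3	2012-06-13	success	1	10
7	A-7-2	38	30	0.3	2012-06-13	success	1	10
8	B-6	39	31	0.3	2012-06-13	success	2	10
9	B-2	40	32	0.5	2012-06-13	success	1	7
10	B-1	43	34	0.3	2012-06-13	failed	2	0
11	A-3-1	103	86	11.7	2012-03-30	success	1	10
12	B-23	140	116	36.1	2013-04-18	success	1	10
13	B-22	143	115	34.9	2013-04-18	success	1	11
14	A-2-1	159	132	36.0	2012-03-30	success	1	11
15	B-8	162	140	58.1	2010-10-21	success	2	10
16	A-4-1	163	138	46.3	2012-06-13	success	1	32
17	B-21	172	144	63.1	2013-04-18	success	1	11
18	A-6-1	177	146	63.5	2012-06-13	success	2	11
19	B-13	196	167	79.8	2010-05-06	success	1	11
20	B-9	198	205	152.0	2010-05-06	success	1	25
21	A-1-1	216	185	109.8	2012-03-30	success	1	10
22	B-20	235	195	150.5	2010-05-06	success	1	11
23	B-15	240	196	150.8	2010-05-06	success	2	10
24	A-5-1	250	215	164.3	2012-06-13	success	1	10
25	B-19	293	246	280.1	2010-05-08	success	1	10
26	B-24	330	282	578.1	2010-08-30	empty_stomach	0	0
27	B-21 (B)	331	285	572.0	2010-08-31	empty_stomach	0	0
28	B-11	354	290	586.8	2012-09-07	success	1	10
29	B-17	357	314	586.8	2010-05-06	success	2	10
30	B-16	367	324	678.5	2010-05-06	success	1	10
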