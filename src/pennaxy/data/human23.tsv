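name	length_genes	mutation_mean	recomb_mean	is_sex_pair
1	2048	0.051282	2.86	0
2	1280	0.032051	2.69	0
3	1024	0.025641	2.24	0
4	768	0.019231	2.12	0
5	896	0.022436	2.05	0
6	1024	0.025641	1.92	0
7	896	0.022436	1.87	0
8	640	0.016026	1.7	0
9	768	0.019231	1.66	0
10	768	0.019231	1.81	0
11	1280	0.032051	1.58	0
12	1024	0.025641	1.75	0
13	384	0.009615	1.26	0
14	640	0.016026	1.19	0
15	640	0.016026	1.41	0
16	896	0.022436	1.34	0
17	1152	0.028846	1.29	0
18	256	0.006410	1.18	0
19	1408	0.035256	1.08	0
20	512	0.012821	1.08	0
21	256	0.006410	0.62	0
22	512	0.012821	0.74	0
X	896	0.022436	1.8	1
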