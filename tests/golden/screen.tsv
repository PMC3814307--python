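# motif = CTCGAR
# window = 800
# threshold_fold = 3
# post_ds_timepoints = 18,24,48,Q
# pseudocount = 0.5
# both_strands = True
# ratio_basis = size_factors
# seed = 5
# k = 100
rank	gene_id	pearson_r
1	g022	0.961406
2	g001	0.946862
3	g004	0.946324
4	g023	0.942962
5	g048	0.938403
6	g075	0.934065
7	g055	0.929891
8	g128	0.927727
9	g065	0.926318
10	g116	0.925056
11	g131	0.924468
12	g051	0.923336
13	g026	0.920874
14	g134	0.918126
15	g105	0.917869
16	g127	0.916114
17	g033	0.915704
18	g161	0.913661
19	g095	0.913211
20	g096	0.911537
21	g149	0.911533
22	g166	0.910232
23	g042	0.909725
24	g076	0.909304
25	g173	0.907379
26	g110	0.906115
27	g158	0.904306
28	g188	0.902991
29	g070	0.902637
30	g083	0.901044
31	g120	0.900496
32	g167	0.900419
33	g073	0.897439
34	g079	0.896676
35	g194	0.895989
36	g175	0.894691
37	g129	0.893180
38	g034	0.892338
39	g047	0.891691
40	g103	0.886877
41	g009	0.876033
42	g012	0.869984
43	g008	0.866607
44	g198	0.864133
45	g179	0.855898
46	g125	0.663608
47	g136	0.660797
48	g141	0.632388
49	g099	0.628993
50	g123	0.606099
51	g160	0.565290
52	g091	0.548175
53	g171	0.528928
54	g020	0.518927
55	g199	0.516044
56	g165	0.506651
57	g069	0.505642
58	g159	0.503463
59	g041	0.502725
60	g174	0.458476
61	g007	0.457137
62	g114	0.440697
63	g152	0.439212
64	g061	0.427286
65	g025	0.410527
66	g133	0.405200
67	g170	0.388738
68	g138	0.329726
69	g071	0.325185
70	g029	0.324988
71	g027	0.321030
72	g094	0.285178
73	g200	0.279931
74	g176	0.269705
75	g182	0.265145
76	g050	0.256654
77	g163	0.250349
78	g054	0.242433
79	g089	0.242334
80	g181	0.242098
81	g185	0.232813
82	g117	0.226930
83	g013	0.226051
84	g190	0.218306
85	g195	0.211900
86	g039	0.207561
87	g015	0.168836
88	g093	0.161453
89	g024	0.144101
90	g044	0.138830
91	g040	0.100577
92	g057	0.098372
93	g111	0.091569
94	g063	0.061183
95	g157	0.060237
96	g177	0.023685
97	g155	0.013931
98	g092	-0.007773
99	g106	-0.011216
100	g043	-0.027293
101	g011	-0.038604
102	g146	-0.071183
103	g140	-0.093206
104	g077	-0.149340
105	g037	-0.164160
106	g056	-0.173122
107	g046	-0.189042
108	g108	-0.219883
109	g086	-0.224080
110	g084	-0.234491
111	g074	-0.265301
112	g002	-0.300790
113	g072	-0.334536
114	g156	-0.338510
115	g109	-0.343325
116	g014	-0.363810
117	g150	-0.365802
118	g164	-0.376375
119	g180	-0.377328
120	g118	-0.387560
121	g045	-0.402480
122	g122	-0.419881
123	g062	-0.445390
124	g085	-0.445820
125	g107	-0.446367
126	g104	-0.446651
127	g060	-0.453154
128	g139	-0.459047
129	g183	-0.470407
130	g142	-0.532358
131	g006	-0.532473
132	g097	-0.555098
133	g115	-0.572027
134	g080	-0.586537
135	g148	-0.602596
136	g168	-0.607780
137	g186	-0.610638
138	g031	-0.617325
139	g112	-0.618135
140	g113	-0.633697
141	g064	-0.634449
142	g147	-0.638156
143	g087	-0.645048
144	g101	-0.652177
145	g154	-0.659795
146	g049	-0.663921
147	g035	-0.668033
148	g059	-0.685898
149	g162	-0.695538
150	g153	-0.705512
151	g151	-0.719393
152	g100	-0.736646
153	g119	-0.746371
154	g102	-0.748685
155	g082	-0.752219
156	g068	-0.752995
157	g028	-0.754087
158	g191	-0.757429
159	g172	-0.758828
160	g178	-0.761154
161	g192	-0.790587
162	g132	-0.793097
163	g144	-0.793858
164	g130	-0.796263
165	g032	-0.798795
166	g081	-0.802123
167	g196	-0.802381
168	g193	-0.807038
169	g098	-0.815746
170	g078	-0.819361
171	g038	-0.821133
172	g145	-0.821170
173	g005	-0.821432
174	g184	-0.834882
175	g090	-0.843950
176	g088	-0.850498
177	g003	-0.852058
178	g189	-0.853899
179	g126	-0.868695
180	g019	-0.870287
181	g052	-0.870330
182	g067	-0.873589
183	g018	-0.874644
184	g010	-0.874746
185	g197	-0.876270
186	g058	-0.881147
187	g030	-0.884977
188	g016	-0.886179
189	g135	-0.890514
190	g017	-0.893446
191	XBP1	-0.896919
192	g169	-0.899721
193	g187	-0.902193
194	g021	-0.909300
195	g036	-0.910502
196	g143	-0.911950
197	g053	-0.913243
198	g066	-0.913852
199	g137	-0.925834
200	g124	-0.928562
201	g121	-0.936973
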