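site_id	amplicon_id	offset	ref_allele	alt_allele
rs1490413	rs1490413	40	.	.
rs4847034	rs4847034	59	.	.
rs3780962	rs3780962	48	.	.
rs964681	rs964681	47	.	.
rs1498553	rs1498553	40	.	.
rs901398	rs901398	59	.	.
rs2269355	rs2269355	40	.	.
rs4530059	rs4530059	50	.	.
rs2016276	rs2016276	49	.	.
rs2342747	rs2342747	57	.	.
rs2292972	rs2292972	37	.	.
rs938283	rs938283	40	.	.
rs9905977	rs9905977	58	.	.
rs1024116	rs1024116	40	.	.
rs576261	rs576261	37	.	.
rs12997453	rs12997453	40	.	.
rs1005533	rs1005533	40	.	.
rs445251	rs445251	40	.	.
rs221956	rs221956	51	.	.
rs2830795	rs2830795	73	.	.
rs733164	rs733164	47	.	.
rs1355366	rs1355366	40	.	.
rs4364205	rs4364205	70	.	.
rs6444724	rs6444724	47	.	.
rs1979255	rs1979255	50	.	.
rs159606	rs159606	40	.	.
rs338882	rs338882	46	.	.
rs7704770	rs7704770	40	.	.
rs13218440	rs13218440	49	.	.
rs6955448	rs6955448	67	.	.
rs1360288	rs1360288	60	.	.
rs1463729	rs1463729	49	.	.
rs7041158	rs7041158	40	.	.
P256	P256	59	.	.
rs17250845	rs17250845	47	.	.
rs35284970	rs35284970	46	.	.
rs3911	rs3911	40	.	.
HLA-A_s01	HLA-A	5	.	.
HLA-A_s02	HLA-A	10	.	.
HLA-A_s03	HLA-A	15	.	.
HLA-A_s04	HLA-A	20	.	.
HLA-A_s05	HLA-A	25	.	.
HLA-A_s06	HLA-A	30	.	.
HLA-A_s07	HLA-A	35	.	.
HLA-A_s08	HLA-A	40	.	.
HLA-A_s09	HLA-A	45	.	.
HLA-A_s10	HLA-A	50	.	.
HLA-A_s11	HLA-A	55	.	.
HLA-A_s12	HLA-A	60	.	.
HLA-A_s13	HLA-A	65	.	.
HLA-A_s14	HLA-A	70	.	.
HLA-A_s15	HLA-A	174	.	.
HLA-A_s16	HLA-A	179	.	.
HLA-A_s17	HLA-A	184	.	.
HLA-A_s18	HLA-A	189	.	.
HLA-A_s19	HLA-A	194	.	.
HLA-A_s20	HLA-A	199	.	.
HLA-A_s21	HLA-A	204	.	.
HLA-A_s22	HLA-A	209	.	.
HLA-A_s23	HLA-A	214	.	.
HLA-A_s24	HLA-A	219	.	.
HLA-A_s25	HLA-A	224	.	.
HLA-A_s26	HLA-A	229	.	.
HLA-A_s27	HLA-A	234	.	.
HLA-A_s28	HLA-A	239	.	.
HLA-B_s01	HLA-B	5	.	.
HLA-B_s02	HLA-B	21	.	.
HLA-B_s03	HLA-B	37	.	.
HLA-B_s04	HLA-B	53	.	.
HLA-B_s05	HLA-B	70	.	.
HLA-B_s06	HLA-B	85	.	.
HLA-B_s07	HLA-B	101	.	.
HLA-B_s08	HLA-B	117	.	.
HLA-B_s09	HLA-B	133	.	.
HLA-B_s10	HLA-B	150	.	.
Chr7q11_s01	Chr7q11	5	.	.
Chr7q11_s02	Chr7q11	18	.	.
Chr7q11_s03	Chr7q11	31	.	.
Chr7q11_s04	Chr7q11	44	.	.
Chr7q11_s05	Chr7q11	57	.	.
Chr7q11_s06	Chr7q11	70	.	.
Chr7q11_s07	Chr7q11	144	.	.
Chr7q11_s08	Chr7q11	157	.	.
Chr7q11_s09	Chr7q11	170	.	.
Chr7q11_s10	Chr7q11	183	.	.
Chr7q11_s11	Chr7q11	196	.	.
Chr7q11_s12	Chr7q11	209	.	.
Chr11q22_s01	Chr11q22	5	.	.
Chr11q22_s02	Chr11q22	26	.	.
Chr11q22_s03	Chr11q22	48	.	.
Chr11q22_s04	Chr11q22	70	.	.
Chr11q22_s05	Chr11q22	121	.	.
Chr11q22_s06	Chr11q22	137	.	.
Chr11q22_s07	Chr11q22	153	.	.
Chr11q22_s08	Chr11q22	169	.	.
Chr11q22_s09	Chr11q22	186	.	.
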