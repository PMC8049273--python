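amplicon_id	chrom	start	stop	size	annotation
rs1490413	chr1	4367241	4367415	175
rs4847034	chr1	105717572	105717689	118
rs3780962	chr10	17193291	17193386	96
rs964681	chr10	132698373	132698467	95
rs1498553	chr11	5708942	5709103	162
rs901398	chr11	11096160	11096278	119
rs2269355	chr12	6945833	6946005	173
rs4530059	chr14	104769098	104769197	100
rs2016276	chr15	24571747	24571845	99
rs2342747	chr16	5868655	5868769	115
rs2292972	chr17	80765753	80765827	75
rs938283	chr17	77468418	77468592	175
rs9905977	chr17	2919336	2919452	117
rs1024116	chr18	75432299	75432467	169
rs576261	chr19	39559774	39559848	75
rs12997453	chr2	182413125	182413299	175
rs1005533	chr20	39487029	39487201	173
rs445251	chr20	15124851	15125009	159
rs221956	chr21	43606946	43607048	103
rs2830795	chr21	28608067	28608212	146
rs733164	chr22	27816739	27816833	95
rs1355366	chr3	190806053	190806219	167
rs4364205	chr3	32417580	32417720	141
rs6444724	chr3	193207331	193207425	95
rs1979255	chr4	190318032	190318131	100
rs159606	chr5	17374818	17374977	160
rs338882	chr5	178690682	178690774	93
rs7704770	chr5	159487871	159488033	163
rs13218440	chr6	12059906	12060004	99
rs6955448	chr7	4310289	4310423	135
rs1360288	chr9	128967996	128968115	120
rs1463729	chr9	126881396	126881493	98
rs7041158	chr9	27985851	27986020	170
P256	chrY	8685171	8685289	119
rs17250845	chrY	8418867	8418960	94
rs35284970	chrY	2734829	2734921	93
rs3911	chrY	21733328	21733502	175
HLA-A	chr6	2911156	2911140	245	Haplotype
HLA-B	chr6	31319491	31319646	156	Haplotype
Chr7q11	chr7	64895160	64895374	215	Haplotype
Chr11q22	chr11	99491336	99491527	192	Haplotype
rs334&rs33930165	chr11	5226980	5227053	74	HBB
rs11393960	chr7	117559481	117559645	165	CFTR
rs75527207&rs74597325	chr7	117587771	117587870	100	CFTR
rs121907954	chr15	72350490	72350617	128	HEXA
rs387906309	chr15	72346528	72346691	164	HEXA
rs147324677	chr15	72346182	72346293	112	HEXA
rs138659167	Chr11	71146795	71146921	127	DHCR7
rs104894299&rs761584017	Chr11	47469333	47469720	388	RASPN
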