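variant_id	amplicon_id	offset	var_type	del_len	gene
rs334	rs334&rs33930165	36	snv	0	HBB
rs33930165	rs334&rs33930165	37	snv	0	HBB
rs11393960	rs11393960	80	del	3	CFTR
rs75527207	rs75527207&rs74597325	45	snv	0	CFTR
rs74597325	rs75527207&rs74597325	52	snv	0	CFTR
rs121907954	rs121907954	64	snv	0	HEXA
rs387906309	rs387906309	80	del	4	HEXA
rs147324677	rs147324677	56	snv	0	HEXA
rs138659167	rs138659167	63	snv	0	DHCR7
rs104894299	rs104894299&rs761584017	60	snv	0	RASPN
rs761584017	rs104894299&rs761584017	330	snv	0	RASPN
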