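snp	chr	pos	ea	oa	eaf	beta	se	pval	n
rs1121980	16	NA	A	G	NA	0.016	0.0135	0.2379	72517
rs1260326	2	NA	C	T	NA	-0.022	0.0138	0.1057	72517
rs13389219	2	NA	T	C	NA	0.004	0.0136	0.7920	72517
rs2340550	19	NA	G	A	NA	-0.009	0.0143	0.5494	72517
rs3799260	6	NA	T	C	NA	0.004	0.0171	0.8049	72517
rs62621812	7	NA	A	G	NA	-0.008	0.0435	0.8495	72517
rs791600	7	NA	A	G	NA	0.039	0.0136	0.0043	72517
rs900399	3	NA	G	A	NA	0.021	0.0136	0.1184	72517
rs972283	7	NA	G	A	NA	-0.009	0.0135	0.5017	72517
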