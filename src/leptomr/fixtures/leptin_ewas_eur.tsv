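snp	chr	pos	ea	oa	eaf	beta	se	pval	n
rs1121980	16	NA	A	G	0.432	0.055	0.007	7.7e-17	50321
rs1260326	2	NA	C	T	0.607	0.032	0.007	1.7e-06	50321
rs13389219	2	NA	T	C	0.394	0.046	0.007	7.3e-11	50321
rs2340550	19	NA	G	A	0.685	-0.008	0.007	2.8e-01	50321
rs3799260	6	NA	T	C	0.818	-0.024	0.008	3.8e-03	50321
rs62621812	7	NA	A	G	0.031	-0.098	0.018	8.2e-08	50321
rs791600	7	NA	A	G	0.411	-0.043	0.007	1.4e-09	50321
rs900399	3	NA	G	A	0.396	-0.033	0.007	2.4e-06	50321
rs972283	7	NA	G	A	0.521	-0.041	0.006	1.1e-10	50321
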