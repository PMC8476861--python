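snp	chr	pos	ea	oa	eaf	beta	se	pval	n
rs1121980	16	NA	A	G	0.432	0.005	0.007	4.5e-01	50321
rs1260326	2	NA	C	T	0.607	0.048	0.007	4.3e-13	50321
rs13389219	2	NA	T	C	0.394	0.053	0.007	1.1e-13	50321
rs2340550	19	NA	G	A	0.685	-0.016	0.007	2.6e-02	50321
rs3799260	6	NA	T	C	0.818	-0.038	0.008	3.8e-06	50321
rs62621812	7	NA	A	G	0.031	-0.127	0.018	2.8e-12	50321
rs791600	7	NA	A	G	0.411	-0.063	0.007	5.4e-19	50321
rs900399	3	NA	G	A	0.396	-0.040	0.007	9.2e-09	50321
rs972283	7	NA	G	A	0.521	-0.056	0.006	3.8e-18	50321
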