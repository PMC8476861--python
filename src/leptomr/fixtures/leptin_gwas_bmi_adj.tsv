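snp	chr	pos	ea	oa	eaf	beta	se	pval	n
rs10487505	7	128220110	G	C	0.50	0.029	0.004	2.0e-12	32161
rs6071166	20	NA	C	A	0.37	0.024	0.004	1.8e-08	32161
rs780093	2	NA	C	T	0.61	0.024	0.004	3.8e-10	32161
rs8043757	16	NA	T	A	0.40	0.001	0.004	8.4e-01	32161
rs900400	3	NA	T	C	0.60	0.021	0.004	1.2e-07	32161
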