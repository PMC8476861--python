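snp	chr	pos	ea	oa	eaf	beta	se	pval	n
rs10487505	7	128220110	G	C	NA	-0.032	0.0135	0.0184	72517
rs6071166	20	NA	C	A	NA	-0.029	0.0141	0.0378	72517
rs780093	2	NA	C	T	NA	-0.024	0.0138	0.0778	72517
rs8043757	16	NA	T	A	NA	0.023	0.0136	0.0925	72517
rs900400	3	NA	T	C	NA	-0.021	0.0136	0.1204	72517
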