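snp_id	gene	effect_allele	beta
rs247617	CETP	C	-0.111
rs1077834	LIPC	A	-0.033
rs10096633	LPL	G	-0.042
rs189069311	APOA5	A	-0.080
rs255054	LCAT	A	-0.042
rs6601299	PPP1R3B	A	-0.063
rs4810479	PLTP	G	-0.029
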