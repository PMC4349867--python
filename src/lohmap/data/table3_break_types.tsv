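strain	genotype	uv_dose	selected_scb	selected_dscb	unselected_scb	unselected_dscb	total_scb	total_dscb
PG311	WT	1	31	10			31	10
PG311	WT	15	5	12	76	106	92	118
YYy23.4	rad14	1	7	2	58	18	65	20
YYy76.14	mus81	15	2	5	27	38	29	43
YYy71	yen1	15	2	10	46	48	48	58
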