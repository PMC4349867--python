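strain	genotype	uv_dose	interstitial	crossovers	bir	total_loh	sectors	indels	ploidy_changes
PG311	WT	1	3	1	0	4	10	0	0
PG311	WT	15	141	50	10	201	20	0	0
YYy23.4	rad14	1	47	18	16	81	12	4	0
YYy76.14	mus81	15	54	7	6	67	7	0	1
YYy71	yen1	15	68	28	3	99	13	1	0
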