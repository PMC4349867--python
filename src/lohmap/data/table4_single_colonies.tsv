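strain	genotype	interstitial	co_bir	total_loh	colonies	interstitial_indels	terminal_indels	ploidy_changes
YYy23.4	rad14	46	26	72	21	2	2	1
YYy47.6	rad14 mus81	13	17	30	24	3	1	0
YYy83	rad14 yen1	30	22	52	18	3	0	1
YYy69	rad14 mms2	61	55	116	21	4	0	3
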