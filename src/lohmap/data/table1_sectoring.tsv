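strain	genotype	sup4_location	uv_dose	sectored	total	freq_fixed	baseline
PG311_V_0	WT	V	0			1.1e-6
PG311_V_1	WT	V	1	47	45544		PG311_V_0
PG311_V_15	WT	V	15	36	7194		PG311_V_0
JSC25_IV_0	WT	IV	0	55	1761664
JSC25_IV_1	WT	IV	1	18	2564		JSC25_IV_0
JSC25_IV_15	WT	IV	15	110	1420		JSC25_IV_0
rad14_V_0	rad14	V	0	0	22797
rad14_V_1	rad14	V	1	23	4853		PG311_V_0
rad14_IV_0	rad14	IV	0	20	144771
rad14_IV_1	rad14	IV	1	99	3216		rad14_IV_0
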