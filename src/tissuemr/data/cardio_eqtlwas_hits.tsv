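tag_snp	genes	trait	n	beta	se	p	p_as_printed
rs646776	SORT1;CELSR2;PSRC1	Total cholesterol	4543	-0.099	0.016	1.10e-9	1.10e-9
rs646776	SORT1;CELSR2;PSRC1	LDL cholesterol	4543	-0.110	0.015	7.74e-14	7.74e-14
rs646776	SORT1;CELSR2;PSRC1	ApoB	4546	-2.695	0.328	2.66e-16	2.66e-16
rs12129500	IL6R	IL-6	4503	-0.126	0.018	4.96e-12	4.96e-12
rs11693654	ADCY3;NCOA1;CENPO	BMI	6387	0.200	0.036	3.57e-8	3.57e-8
rs80026582	LPL	Triglycerides	4334	-0.101	0.018	1.49e-8	1.49e-8
rs80026582	LPL	VLDL cholesterol	4334	-0.100	0.018	1.57e-8	1.57e-8
rs600038	ABO	IL-6	4496	-0.207	0.021	4.12e-22	4.12e+22
rs174538	FADS1;FADS2;TMEM258	Total cholesterol	4539	-0.080	0.015	5.03e-8	5.03e-8
rs2727784	APOA1;TAGLN	ApoA1	4018	3.047	0.468	8.05e-11	8.05e-11
rs10419998	GATAD2A;MAU2;TM6SF2	ApoB	4404	-2.024	0.376	7.96e-8	7.96e-8
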