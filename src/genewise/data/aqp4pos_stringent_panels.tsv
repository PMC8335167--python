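method	gene	position	nsnps	p
sum	ATP6V1G2	chr6:31620699..31621843	11	1E-06
sum	ATP6V1G2-DDX39B	chr6:31530219..31546848	20	1E-06
sum	CFB	chr6:32022003..32027809	18	1E-06
sum	CLIC1	chr6:31810689..31812273	4	1E-06
sum	EHMT2	chr6:31956199..31972526	16	1E-06
sum	HLA-DQA1	chr6:32717784..32717784	22	1E-06
sum	MB21D1	chr6:73423711..73452297	29	1E-06
sum	MSH5	chr6:31816126..31837338	34	1E-06
sum	MSH5-SAPCD1	chr6:31739948..31764850	36	1E-06
sum	SLC44A4	chr6:31942176..31954213	44	1E-06
sum	STK19_1	chr6:31971175..31981446	10	1E-06
sum	TNXB_2	chr6:32041153..32109338	85	1E-06
sum	SLC17A5	chr6:74361136..74419621	334	2E-06
set	AGER	chr6:32257794..32259972	5	1.09E-06
set	BTNL2	chr6:32470908..32482618	35	1.43E-06
set	C6orf10	chr6:32368537..32447625	213	1.88E-09
set	C6orf136	chr6:30726885..30726885	1	7.09E-08
set	C6orf27	chr6:31841629..31850569	4	6.22E-07
set	C6orf48	chr6:31912625..31915519	4	1E-08
set	CFB	chr6:32022003..32027809	15	1.2E-06
set	EGFL8	chr6:32242488..32242488	1	1.9E-08
set	EHMT2	chr6:31956199..31972526	10	1.81E-09
set	HLA-DQA1	chr6:32717784..32717784	1	3.29E-09
set	HLA-DRA	chr6:32515687..32520787	37	8.77E-10
set	MSH5	chr6:31816126..31837338	19	3.78E-10
set	PBX2	chr6:32262263..32265617	4	3.54E-07
set	PRRT1	chr6:32225949..32225949	1	2.21E-08
set	RNF5	chr6:32254470..32256381	6	9.36E-08
set	SKIV2L	chr6:32035321..32045016	17	6.39E-07
set	SLC44A4	chr6:31942176..31954213	19	2.82E-06
set	STK19	chr6:32048876..32055439	7	2.24E-13
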