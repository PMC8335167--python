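gene	position	nsnp_sum	p_sum	nsnp_set	p_set	p_meta
RGS1	chr1:190811722..190815166	9	0.001563	25	0.000215	5.35E-06
COL8A2	chr1:36338171..36338204	2	4.32E-05	15	0.015598	1.02E-05
AGTPBP1	chr9:87354033..87545005	115	0.000611	413	0.00196	1.75E-05
SYT9	chr11:7232814..7446395	376	0.02569	743	0.000047	1.77E-05
SGIP1	chr1:66772691..66982406	374	0.002918	654	0.000461	1.95E-05
CEACAM4	chr19:46817929..46824888	10	0.03613	31	0.000043	2.23E-05
INTS5	chr11:62177128..62177128	1	0.000506	5	0.00558	3.89E-05
RAD51AP2	chr2:17557392..17562159	7	0.003099	36	0.000931	3.97E-05
CDR2L	chr17:70496373..70513013	6	0.000389	20	0.00889	4.7E-05
ZNF652	chr17:44728416..44791811	39	0.005543	148	0.000784	5.8E-05
WDR86	chr7:150709151..150736999	23	0.008985	101	0.000599	7.07E-05
HSD11B1	chr1:207927291..207973298	28	0.005835	76	0.000976	7.45E-05
SYCE1	chr10:135217645..135231917	54	0.001929	100	0.00354	8.81E-05
SSFA2	chr2:182469362..182502779	16	0.003418	48	0.00205	9.02E-05
WT1	chr11:32366048..32412429	65	0.002659	159	0.00276	9.41E-05
RAX2	chr19:3720253..3720899	4	0.001959	16	0.004	1E-04
CAPG	chr2:85475570..85489706	11	0.009872	77	0.000851	0.000107
PIGX	chr3:197926529..197946898	12	0.003838	75	0.00228	0.000111
RPS3	chr11:74788237..74794135	4	0.001819	31	0.00564	0.000128
PGRMC2	chr4:129414746..129427709	5	0.003674	19	0.0028	0.000128
TRAF3IP3	chr1:207996202..208020329	32	0.00363	61	0.0033	0.000148
PTPLAD1	chr15:63611672..63657183	24	0.005597	89	0.00231	0.000158
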