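gene	position	nsnp_set	p_set	nsnp_sum	p_sum	p_meta
MSH5	chr6:31816126..31837338	19	3.78E-10	34	1.00E-06	1.38E-14
EHMT2	chr6:31956199..31972526	10	1.81E-09	16	1.00E-06	6.31E-14
HLA-DQA1	chr6:32717784..32717784	1	3.29E-09	22	1.00E-06	1.13E-13
CFB	chr6:32022003..32027809	15	1.20E-06	18	1.00E-06	3.42E-11
SLC44A4	chr6:31942176..31954213	19	2.82E-06	44	1.00E-06	7.77E-11
C6orf10	chr6:32368537..32447625	213	1.88E-09	14	0.0027	1.37E-10
CLIC1	chr6:31810689..31812273	2	7.76E-06	4	1.00E-06	2.06E-10
SLC17A5	chr6:74361136..74419621	92	4.78E-06	334	2.00E-06	2.52E-10
HIST1H1B	chr6:27943197..27943251	2	8.83E-06	12	1.20E-05	2.54E-09
HIST1H2BL	chr6:27883653..27883676	2	2.57E-05	6	2.10E-05	1.21E-08
HIST1H2AL	chr6:27941153..27941153	1	2.66E-05	9	2.30E-05	1.36E-08
ATP6V1G2	chr6:31620699..31621843	5	0.003494	11	1.00E-06	7.15E-08
ZSCAN16	chr6:28200582..28205172	8	7.64E-05	14	5.40E-05	8.38E-08
BTN3A2	chr6:26473574..26486128	39	0.000377	89	2.20E-05	1.62E-07
EEF1A1	chr6:74283039..74286513	7	9.38E-05	20	9.40E-05	1.72E-07
MTO1	chr6:74228188..74266790	17	0.000618	78	2.30E-05	2.71E-07
VARS	chr6:31856799..31870822	5	1.10E-05	2	0.00213	4.36E-07
C6orf15	chr6:31187055..31188078	9	0.000135	24	0.000181	4.54E-07
ARSI	chr5:149656490..149660452	3	0.000152	18	0.000197	5.48E-07
ZFP57	chr6:29750488..29756485	16	0.000276	17	0.000148	7.37E-07
BTN2A1	chr6:26566244..26576639	20	0.003007	66	3.60E-05	1.84E-06
C2	chr6:32003952..32019988	12	0.001923	41	8.30E-05	2.66E-06
LTA	chr6:31648120..31648763	5	0.001067	8	0.000202	3.52E-06
HIST1H3J	chr6:27966400..27966400	1	0.000498	6	0.000467	3.79E-06
PSORS1C1	chr6:31190939..31215712	65	0.005206	149	6.40E-05	5.3E-06
GLS	chr2:191457280..191537657	43	0.000938	108	0.000379	5.63E-06
CDSN	chr6:31190939..31192771	17	0.001358	35	0.000402	8.42E-06
APPL1	chr3:57238434..57282001	17	0.000839	63	0.000788	1.01E-05
NFKBIL1	chr6:31623742..31633891	12	0.003355	32	0.000241	1.22E-05
ZNF165	chr6:28154652..28163474	8	0.003189	29	0.00042	1.95E-05
ZKSCAN3	chr6:28426460..28441375	24	0.008439	64	0.000175	2.13E-05
HSPA1A	chr6:31891486..31891486	1	0.000957	2	0.00157	2.16E-05
C6orf203	chr6:107458491..107478905	17	0.000463	87	0.00427	2.79E-05
ZMYND19	chr9:139597070..139602897	4	0.000315	19	0.00638	2.83E-05
EIF3F	chr11:7965996..7973800	16	0.004203	35	0.000498	2.95E-05
PSORS1C2	chr6:31213289..31215066	12	0.004212	16	0.000612	3.57E-05
HRASLS2	chr11:63078313..63086972	5	0.003647	14	0.000846	4.22E-05
KLHL30	chr2:238715095..238725505	11	0.000507	54	0.0069	4.75E-05
CAPN2	chr1:221967442..222030091	65	0.002096	206	0.00187	5.27E-05
CDC16	chr13:114021570..114055715	19	0.003988	90	0.00103	5.51E-05
PKN3	chr9:130508561..130522288	2	0.001899	13	0.00222	5.64E-05
TBCB	chr19:41301630..41306302	5	0.000416	25	0.015898	8.55E-05
TJP2	chr9:70980117..71059730	108	0.007071	418	0.001	9.09E-05
TAP2	chr6:32897785..32914439	65	0.006917	112	0.00111	9.81E-05
RBBP6	chr16:24458431..24490907	30	0.005909	75	0.00134	0.000101
CYP2A6	chr19:46042434..46046373	3	0.001634	26	0.00522	0.000108
PSMB9	chr6:32930164..32934963	14	0.002805	23	0.00336	0.000118
TCP10	chr6:167715748..167716814	4	0.004822	28	0.00241	0.000144
POLA2	chr11:64786765..64821494	15	0.003271	36	0.00391	0.000157
LST1	chr6:31662586..31664560	6	0.0259	7	0.000496	0.000158
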