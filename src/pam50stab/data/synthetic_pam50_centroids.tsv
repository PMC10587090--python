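gene	Basal	HER2E	LumA	LumB	Normal
ANLN	0.8845	0.6211	-0.2578	0.5014	-0.6824
BIRC5	0.3961	0.5326	-0.3099	0.1503	-0.6831
CCNB1	0.8032	0.5463	-0.2041	0.6771	-0.1201
CCNE1	0.669	0.1962	-0.4455	0.2999	-0.9455
CDC20	0.7125	0.3249	-0.6963	0.5157	-0.487
CDC6	0.6861	0.3912	-0.7729	0.2104	-0.9263
CENPF	1.1497	0.4591	-0.6488	0.8452	-0.3745
CEP55	0.6965	0.7401	-0.7963	0.5617	-0.754
EXO1	0.4882	-0.091	-0.6622	0.549	-0.9676
KIF2C	0.7894	0.5307	-0.6417	0.6399	-0.4632
MELK	0.4392	0.0841	-0.4827	0.4998	-0.7966
MKI67	0.5618	0.4295	-1.0179	0.7833	-0.5668
MYBL2	0.5105	0.0439	0.0389	0.7276	-0.5589
NDC80	0.8008	0.3275	-0.554	0.3634	-0.7358
NUF2	0.9778	0.398	-0.2409	1.1101	-0.4387
ORC6	0.8731	0.2072	-0.4799	0.4446	-0.8838
PTTG1	0.9612	0.4725	-0.3158	0.21	-0.5975
RRM2	0.8524	0.7245	-0.2763	0.4172	-0.098
TYMS	1.0107	0.2442	-0.4694	0.297	-0.49
UBE2C	0.4666	0.3883	-0.4563	0.5264	-0.5675
UBE2T	0.6886	0.3451	-0.5576	0.8536	-0.6383
ESR1	-1.1987	-0.7566	0.8043	0.7034	-0.1472
FOXA1	-1.1927	-0.9388	0.6474	0.4368	0.2867
PGR	-0.8972	-0.633	1.3887	0.7637	-0.1137
BCL2	-1.0136	-0.6193	0.8764	0.5622	0.3291
SLC39A6	-0.9731	-0.2596	0.8484	0.3784	0.3672
MAPT	-0.9804	-0.5601	1.0105	0.6633	0.0956
NAT1	-1.1515	-0.7009	0.9458	0.4615	-0.1903
MLPH	-0.734	-0.6924	1.241	0.8403	0.25
CXXC5	-1.1481	-0.7549	0.4215	0.8364	0.0815
CDH3	0.8832	-0.1257	-0.1509	-0.3135	1.3156
KRT17	0.6447	-0.3462	-0.5123	-0.5465	0.7867
KRT5	1.3579	0.1015	0.2549	-0.2285	1.1685
KRT14	0.8952	-0.6209	-0.4368	-0.7397	0.85
MIA	0.6557	-0.4394	-0.6397	-0.5976	0.954
SFRP1	0.5186	-0.2716	-0.0895	-0.9564	0.9008
EGFR	0.6673	-0.3025	-0.0746	-0.477	0.5932
FOXC1	0.9523	-0.3363	-0.7323	-0.3083	0.7023
ERBB2	-0.2794	1.1396	-0.167	0.0428	-0.2041
GRB7	0.1068	1.5847	0.5369	0.0629	0.2203
ACTR3B	0.6197	0.3758	-0.1723	-0.2515	0.3378
PHGDH	1.0588	-0.0962	-0.0794	-0.0306	-0.1232
GPR160	-0.9526	-0.0114	0.3398	0.0239	-0.1499
TMEM45B	-0.7822	0.4285	0.6782	0.269	0.1636
FGFR4	-0.0565	1.2586	0.0234	0.3987	-0.1891
MYC	0.532	0.2355	-0.3199	0.2516	0.0545
MMP11	-0.2464	0.3924	0.0621	0.3052	-0.4592
BAG1	-0.2536	-0.0416	0.3914	0.1072	0.1234
MDM2	-0.2006	0.0216	0.3292	0.0257	0.33
BLVRA	0.3717	-0.1606	0.2742	-0.0193	0.2373
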