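# Published per-sample read accounting and subsampling-standardized diversity
# panel for the South China Sea paired DNA/RNA survey (sites F3 and H7,
# summer 2014; 31 libraries as printed). Sample ids encode site.depth + acid
# (D = rRNA gene, R = rRNA transcript); 1K/15K/2K/39K = 1000/1500/2000/3900 m.
sample	clean_reads	metazoa_pct	protist_reads	metazoan_otus	protist_otus	otus_std	chao1_std	ace_std	shannon_std	simpson_std	pd_std
F3.25D	54581	13.0	47484	64	1371	1065	1418	1417	6.34	0.015	163.15
F3.75D	34495	18.5	28117	67	1125	1031	1346	1331	7.25	0.039	159.29
F3.200D	35586	16.2	29805	50	1262	1097	1491	1456	7.09	0.031	164.15
F3.300D	77840	5.0	73968	75	1459	952	1429	1398	5.54	0.012	150.66
F3.500D	99944	9.1	90828	76	1385	836	1201	1218	5.26	0.013	129.84
F3.1KD	150687	4.7	143668	70	1323	633	918	968	4.47	0.013	111.00
F3.15KD	148897	5.1	141365	78	1268	599	914	1022	3.40	0.009	110.85
F3.2KD	174306	2.9	169189	67	1381	669	1083	1151	4.16	0.009	120.26
F3.25R	29060	8.7	26522	49	1172	1092	1380	1401	8.06	0.105	173.86
F3.75R	22481	10.1	20204	43	918	918	1239	1196	7.67	0.093	148.53
F3.200R	24836	12.3	21772	39	1032	1007	1288	1246	7.12	0.022	157.56
F3.300R	31288	4.2	29968	45	1147	1011	1413	1337	7.00	0.031	158.61
F3.500R	40374	7.5	37332	50	1129	942	1215	1213	7.03	0.042	154.67
F3.1KR	52331	4.8	49802	52	1161	867	1120	1118	5.92	0.016	141.83
F3.15KR	67120	3.6	64716	53	1026	665	1037	1081	3.91	0.005	119.70
F3.2KR	63444	2.8	61696	53	1111	771	1048	1100	5.89	0.029	134.28
H7.5D	38986	41.5	22815	65	1119	1082	1426	1421	7.62	0.052	162.61
H7.25D	35680	32.7	24013	60	1320	1272	1702	1647	7.88	0.052	180.16
H7.75D	52050	11.1	46285	62	1451	1098	1526	1497	6.84	0.028	166.21
H7.200D	70027	17.9	57510	85	1504	1078	1509	1486	6.49	0.021	164.96
H7.500D	31488	11.2	27946	59	1155	1051	1420	1450	6.80	0.030	161.60
H7.1KD	122774	23.4	94077	83	1398	836	1269	1335	5.11	0.012	133.54
H7.15KD	134465	12.1	118161	80	1330	664	999	1065	4.26	0.011	115.79
H7.39KD	118192	7.1	109746	94	1498	810	1329	1295	5.13	0.013	140.79
H7.5R	40821	21.8	31924	66	1003	901	1230	1199	7.48	0.081	147.53
H7.25R	55457	42.1	32131	70	1155	1027	1429	1404	7.48	0.061	162.22
H7.75R	56374	11.6	49842	68	1300	994	1352	1377	6.81	0.029	161.07
H7.200R	50270	17.2	41628	80	1238	985	1398	1377	6.42	0.022	160.56
H7.500R	37634	5.0	35734	61	965	789	1194	1134	6.34	0.029	133.99
H7.1KR	114111	4.9	108558	66	1187	679	1021	1087	4.93	0.019	121.41
H7.15KR	133136	7.3	123380	67	1127	579	976	1016	4.02	0.010	111.64
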