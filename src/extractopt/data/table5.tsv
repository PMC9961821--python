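no	class	name	formula	observed_neg	observed_pos	calculated	fragments	ce	cl	first_time
1	Phenolic acids and derivatives	Coumalic acid	C6H4O4	139.0050		139.0031	111.01;95.01	20	3	1
2	Phenolic acids and derivatives	Hydroxybenzoylhexose	C13H16O8	299.0876		299.0884	281.06;237.04;179.03;163.06;137.02	20	2	0
3	Phenolic acids and derivatives	Coumaroyl hexose	C15H18O8	325.0929		325.0923	163.03;147.04	10	2	0
4	Phenolic acids and derivatives	Caffeoylshikimic acid	C16H16O8	335.0776	337.0932	335.0772	179.01;161.03;155.03;137.05	20	2	0
5	Phenolic acids and derivatives	Caffeic acid hexoside	C15H18O9	341.1100		341.0872	215.03;179.06;161.04	20	2	0
6	Phenolic acids and derivatives	Caffeic acid derivatives	C18H18O9	377.0885		377.0878	341.10;215.03;179.06;161.04	10	2	0
7	Phenolic acids and derivatives	Dicaffeoyl shikimic acid	C22H26O13	497.1297		497.1295	335.01;178.02;135.02	20	2	0
8	Phenolic acids and derivatives	Hebitol II	C21H30O14	505.1603		505.1557	341.08;325.09;179.03;163.03	30	3	1
9	Phenolic acids and derivatives	1,2-di-(syringoyl)-hexoside	C24H28O14	539.1377	541.1533	539.1401	359.09;341.08;197.04;153.05	30	3	1
10	Flavonoids and derivatives	Chrysoeriol	C13H16O8	299.0561	301.0717	299.0555	285.03;255.02;153.01;147.04;135.03;125.03	20	2	0
11	Flavonoids and derivatives	Quercetin	C15H10O7	301.0354	303.0510	301.0348	273.02;257.03;229.05;179.01;151.01	20	2	0
12	Flavonoids and derivatives	Dihydrokaempferol hexoside	C21H22O11	449.1089		449.1083	287.04;269.05;259.06;169.01;151.01	20	2	0
13	Flavonoids and derivatives	Isoquercitrin	C21H20O12	463.0878		463.0876	301.05;268.01;179.02;151.01	20	2	0
14	Flavonoids and derivatives	Isorhamnetin hexoside	C22H22O12	477.1035	479.1191	477.1033	315.05;300.01;271.02;255.05;179.05;151.02	20	2	0
15	Flavonoids and derivatives	Luteolin hexosyl sulfate	C21H20O14S	527.0491	529.0647	527.0495	447.05;285.01;241.06	20	2	0
16	Flavonoids and derivatives	Chrysoeriol hexosyl sulfate	C22H22O14S	541.0645	543.0801	541.0652	299.05;284.05;241.02	20	2	0
17	Flavonoids and derivatives	Isoquercitrin sulfate	C21H20O15S	543.0441	545.0597	543.0444	463.05;301.01;268.01;179.02;151.01	20	2	0
18	Flavonoids and derivatives	Apigenin-8-C-(pentosyl) hexoside	C26H28O14	563.1655		563.1400	473.01;443.02;413.05;340.08;311.02	30	2	0
19	Flavonoids and derivatives	Naringin dihydrochalcone	C27H34O14	581.1863		581.1870	436.13;274.08;167.03;149.06;133.06	30	3	1
20	Flavonoids and derivatives	Afzelin gallate	C28H24O14	583.1093		583.1087	297.05;285.04;169.01	20	2	0
21	Flavonoids and derivatives	Luteolin rhamnosyl hexoside	C27H30O15	593.1507		593.1506	447.09;285.03;153.01;135.04	20	2	0
22	Flavonoids and derivatives	Chrysoeriol rhamnosyl hexoside	C28H32O15	607.1669		607.1663	461.10;299.05;284.03;153.01;149.05	20	2	0
23	Flavonoids and derivatives	Quercetin rhamnosyl glucoside	C27H30O16	609.1459		609.1455	463.08;447.09;301.02;151.04	20	2	0
24	Flavonoids and derivatives	Isorhamnetin rhamnosyl glucoside	C28H32O16	623.1617	625.1773	623.1612	477.10;315.05;299.05;165.05	20	2	0
25	Flavonoids and derivatives	Quercetin diglucoside	C27H30O17	625.1410	627.1566	625.1404	463.08;301.01	20	2	0
26	Flavonoids and derivatives	Isorhamnetin diglucoside	C28H32O17	639.1563	641.0612	639.1561	447.01;315.01	20	2	0
27	Flavonoids and derivatives	Luteolin dihexosyl sulfate	C27H30O19S	689.1029		689.1023	519.11;489.10;471.09;399.07;369.06;339.05	20	2	0
28	Flavonoids and derivatives	Luteolin rhamnosyl dihexoside	C33H40O20	755.2046		755.2034	709.16;593.10;575.05;285.01	20	2	0
29	Flavonoids and derivatives	Chrysoeriol rhamnosyl dihexoside	C34H42O20	769.2189		769.2191	623.16;461.10;299.05;284.03;153.02	20	2	0
30	Lignans	Erythro-guaiacylglycerol-beta-syringaresinol ether hexoside	C38H48O17	775.2821		775.2813	613.22;417.14;181.05;151.03	30	3	1
31	Lignans	Erythro-1-(4''-glucoside-3,5-dimethyoxyphenyl)-2-syringaresinoxyl-propane-1,3-diol	C39H50O18	805.2926		805.2919	643.23;417.14;181.05;151.03	30	3	1
32	Sialic acids	2-Deoxy-2,3-dehydro-N-acetylneuraminic acid	C11H17NO8	290.0879		290.0876	230.06;200.05;171.01;128.07	20	3	1
33	Sialic acids	N-acetyl-alpha-neuraminic acid	C11H19NO9	308.0987	310.1143	308.0987	290.09;219.06;200.05;146.08;128.07	20	3	1
34	Sialic acids	6'-Sialyllactose	C23H39NO19	632.2039		632.2044	290.09;200.05;128.07	30	3	1
35	Amino acids	L-proline	C5H9NO2	114.0570		114.0561	70.06	10	2	0
36	Amino acids	Pyroglutamic acid	C5H7NO3	128.0360	130.0416	128.0353	82.3;71.9	10	2	0
37	Amino acids	L-aspartic acid	C4H7NO4	132.0329		132.0302	116.03;88.04	10	2	0
38	Amino acids	Allysine	C6H11NO3	144.0682		144.0666	127.04;126.05;100.07	20	3	1
39	Sugar molecules	Ribonic acid	C5H10O6	165.0421		165.0418	149.04;105.01;87.00;75.00	10	2	0
40	Sugar molecules	L-Galactose	C6H12O6	179.0572		179.0561	161.04;143.03;113.02;101.02	10	2	0
41	Sugar molecules	Mannitol	C6H14O6	181.0725		181.0718	165.01;147.03;129.05;111.00	20	2	0
42	Sugar molecules	Gluconic acid	C6H12O7	195.0522		195.0504	177.05;159.02;129.05;98.90	10	2	0
43	Sugar molecules	Sedoheptulose	C7H14O7	209.0679		209.0680	191.05;179.05;149.04	20	2	0
44	Sugar molecules	Hexose derivative	C12H19O10	323.0977		323.0978	179.05;161.04;143.03;113.02;101.02	10	2	0
45	Sugar molecules	Maltitol	C12H24O11	343.1255		343.1240	283.10;265.09;179.05;161.04;143.03	20	2	0
46	Sugar molecules	Unsaturated digalacturonate	C12H16O12	351.0574	353.0730	351.0569	291.07;273.06;175.02;131.03	20	3	1
47	Sugar molecules	Xylosmaloside	C18H20O9	379.1027	381.1183	379.1029	343.08;217.05;179.05;161.04	20	3	1
48	Carboxylic acids	Fumaric acid	C4H4O4	115.0050		115.0037	71.01	10	2	0
49	Carboxylic acids	Glutaconic acid	C5H6O4	129.0203		129.0203	111.00;85.02	10	2	0
50	Carboxylic acids	Glutaric acid	C5H8O4	131.0355		131.0350	113.00;87.02	10	2	0
51	Carboxylic acids	3-Methylglutaconic acid	C6H8O4	143.0367		143.0361	99.03	20	2	0
52	Carboxylic acids	Methyl glutaric acid	C6H10O4	145.0521		145.0506	127.02;101.02	10	2	0
53	Carboxylic acids	2-Hydroxyglutaric acid	C5H8O5	147.0301		147.0299	129.01;99.03	10	2	0
54	Carboxylic acids	Hydroxymethyl glutaric acid	C6H10O5	161.0459		161.0455	143.03;117.05;99.04	10	2	0
55	Carboxylic acids	Citric acid	C6H8O7	191.0197	193.0353	191.0197	173.00;129.01;111.00	20	2	0
56	Fatty acids	Palmitic acid	C16H32O2	255.2330		255.2330	237.23;211.24;197.22	20	2	0
57	Fatty acids	Linolenic acid	C18H30O2	277.2165		277.2169	259.20;233.22;205.21;179.25;165.23	10	2	0
58	Fatty acids	alpha-Linoleic acid	C18H32O2	279.2331		279.2330	261.22	10	2	0
59	Fatty acids	Oleic acid	C18H34O2	281.2487		281.2486	263.25;181.21;127.25	10	2	0
60	Fatty acids	Hydroxy octadecatrienoic acid	C18H30O3	293.2120		293.0216	275.22	20	3	1
61	Fatty acids	Hydroxy octadecadienoic acid	C18H32O3	295.2276		295.2273	277.23	20	2	0
62	Fatty acids	Hydroxy octadecenoic acid	C18H34O3	297.2433		297.2429	279.23	20	2	0
63	Fatty acids	Dihydroxy octadecadienoic acid	C18H32O4	311.2246	313.2402	311.2239	293.22;275.23	20	2	0
64	Fatty acids	Dihydroxy octadecenoic acid	C18H34O4	313.2381	315.2537	313.2378	295.23;277.25;183.32	20	2	0
65	Fatty acids	Dihydroxy octadecanoic acid	C18H36O4	315.2538	317.2694	315.2535	297.23;279.25	20	2	0
66	Fatty acids	Trihydroxy octadecadienoic acid	C18H32O5	327.2176		327.2171	309.23;291.25;273.23	20	2	0
67	Fatty acids	Trihydroxy octadecenoic acid	C18H34O5	329.2346	331.2502	329.2333	311.25;293.26;275.23	20	2	0
68	Others	Linustatin	C16H27NO11	408.1510	410.1666	408.1506	318.11;246.09;228.08;214.07	20	3	1
69	Others	Norbellidifodin	C13H8O6	259.0240	261.0396	259.0248	241.01;215.12;187.05;171.03	30	3	1
70	Others	1-Deoxynojirimycin hexoside	C12H23NO9	324.1293		324.1295	161.04;144.06;143.03;113.02	30	3	1
71	Others	Oxycoumarin-4-acetic acid methyl ester hexoside	C18H20O10	395.0962		395.0978	233.04;205.05;161.02;133.02	30	3	1
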