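ordinal	designation	start	stop	strand	rt_pcr	wt_bands	pnp_bands
1	trnH	18	125	+	+	1.6,1.8	1.6,1.8,3.7
2	matK	2946	3086	+	+	.	.
3	rps16	4814	5371	+	+	1.3	0.8,1.2,1.3
4	rps16i-1	5426	5581	+	+	0.8,1.1,1.3	0.8,0.9,1.1,1.3
5	rps16i-2	5632	5875	+	NT	NT	NT
6	trnQ	6521	6646	+	+	1.0,1.2	1.1,1.2
7	psbK	6882	7462	-	+	1.2,3.3,3.4	1.3,3.4,3.5
8	psbI	7611	7691	-	-	NT	NT
9	trnS.1	7817	7984	+	+	1.8,3.0,3.2	1.9,3.1,3.3
10	trnG-5'	8644	9004	-	+	1.1,1.8	1.1,1.8,3.7
11	trnG-3'	9244	9484	-	+	.	0.5,0.6,1.0,3.3,3.7
12	trnR.1	9555	9858	-	+	0.2,0.3	.
13	atpA	10342	10536	-	NT	NT	NT
14	atpI	14088	14182	+	+	0.6,1.0	0.2,0.4,0.6,1.0,1.2
15	rpoC2-1	16984	17163	+	NT	NT	NT
16	rpoC2-2	17233	17410	+	NT	NT	NT
17	trnC	27446	27666	-	+	0.6,1.1,1.7	0.5,0.6,1.1,1.7
18	trnC-ycf6int	27807	27956	-	+	.	.
19	trnD	29627	29825	+	NT	NT	NT
20	trnD-trnYint	29939	30070	+	NT	NT	NT
21	trnT.1	31408	31518	-	+	.	0.3,0.9
22	psbD	33106	33456	-	+	.	.
23	trnS.2	35312	35409	+	+	3.3,3.4	3.1,3.4,3.7
24	ycf9	35820	36116	-	+	0.3,0.9,2.0	0.4,0.8,1.0,2.3
25	trnfM	36642	36862	+	+	0.1,0.3,0.4	0.8-1.0smear
26	rps14-psaBint	37250	37327	+	-	NT	NT
27	ycf3-3'	42542	42629	+	+	.	.
28	trnS.3	44827	45050	-	+	1.1	1.2,1.4,1.5,3.0
29	rps4-3'	45294	45358	+	+	1.9	1.9
30	rps4-5'	45747	45929	+	-	.	.
31	trnT.2	46026	46338	+	-	.	.
32	trnL-3'	47417	47670	-	NT	NT	NT
33	ndhK	49260	49386	+	+	.	.
34	ndhC-5'	50269	50469	+	+	.	.
35	ndhC-trnV.1int	50762	50916	+	+	.	0.4,0.7,0.8,1.3
36	trnVi	51688	51884	+	NT	NT	NT
37	trnM	51950	52128	-	NT	NT	NT
38	rbcL-accDint	56584	56822	-	+	0.5,0.6,1.0	0.4,0.5,3.0
39	accD	57949	58056	-	+	0.7,0.8,1.0,1.9	0.4,0.7,1.9
40	accD-psaIint-1	58776	58869	-	+	1.1,1.8	0.4,0.6,0.7,1.1,1.9
41	accD-psaIint-2	59030	59096	-	-	NT	NT
42	ycf10-5'	60756	60963	-	+	.	.
43	ycf10	60983	61159	-	+	1.3,1.7,1.8	1.1,1.3,1.7,1.9
44	ycf10-petAint	61409	61529	-	+	1.0,1.6,1.8	0.9,1.0,1.6,1.8
45	petA	62045	62271	-	+	0.5,1.7	0.5,1.2,1.4,1.8
46	psbJ	63479	63648	+	NT	NT	NT
47	psbL-psbF	63805	64018	+	NT	NT	NT
48	orf31	65708	65805	-	+	.	.
49	trnW	66248	66330	+	+	0.9,1.3,1.8	0.8,0.9,1.2,1.3,1.9,2.9
50	trnP	66330	66701	+	+	1.0,1.1	1.0,1.1,1.9
51	psaJ	66920	67113	-	NT	NT	NT
52	psaJ-rpl33int	67154	67304	-	+	0.3,0.7,1.3,1.4	1.2,1.3,1.4,3.0
53	rpl33	67334	67594	-	+	0.7,1.3,1.4,2.7,3.1	1.2,1.3,1.4,3.0
54	rps18	67784	68222	-	+	1.0,1.4,1.9,3.0	1.2,1.8,1.9,2.8,3.7
55	rpl20	68512	68680	+	NT	NT	NT
56	psbB	73677	73837	-	+	1.7	0.9,1.0,1.7
57	psbB-psbTint	73927	74077	-	+	0.6	0.6,0.7,0.9
58	psbT	74136	74184	-	NT	NT	NT
59	psbN	74249	74380	+	+	2.0,3.3,3.5	2.0,3.3,3.6
60	psbH	74601	74726	-	+	1.1,1.9	1.9
61	petBi	74967	75151	-	+	.	.
62	petD-3'	77431	77604	-	+	.	.
63	rpoA-3'	77967	78098	+	+	.	1.2,1.3,3.3
64	rpoA	78320	78768	+	NT	NT	NT
65	rpoA-5'	78827	78957	+	+	.	.
66	rps11	79166	79359	+	NT	NT	NT
67	rpl36	79502	79858	+	NT	NT	NT
68	rpl14	80723	80895	+	NT	NT	NT
69	rpl2i	85271	85419	+	NT	NT	NT
70	trnI.1	86203	86389	+	+	0.3	0.35,0.4,0.5
71	ycf2.1-1	86644	86764	-	+	0.7	0.75
72	ycf2.1-2	87948	88212	-	+	.	1.2,1.3,3.5
73	ycf2.1-3	88451	88564	-	+	.	.
74	ycf2.1-4	88960	89328	-	+	.	.
75	ycf2.1-5	89445	90769	-	+	1.0	.
76	ycf2.1-6	91158	91564	-	+	.	1.2,1.7
77	ycf2.1-7	91703	92005	-	+	.	.
78	ycf2.1-8	92309	92432	-	+	1.8,3.7	1.1,1.2,1.8,3.8
79	ycf2.1-9	92979	93113	-	+	1.2	0.6,0.7,1.25,1.6,1.7
80	ycf2.1-10	93178	93281	-	+	.	.
81	trnL-ndhBint	94377	94967	+	+	0.4,1.7,3.7	0.6,1.6,1.7,3.7
82	ndhB-3'	95111	95707	+	+	.	.
83	ndhBi	95910	96164	+	NT	NT	NT
84	rps12-5'	98718	98822	+	NT	NT	NT
85	rrn4.5-rrn5int	107905	107963	-	+	.	.
86	ycf1.1-1	109354	109553	-	NT	NT	NT
87	ycf1.1-2	109923	110387	-	+	0.8,0.9,1.3,3.3	0.85,1.3,3.2,3.3
88	ndhF-3'	110389	110488	+	-	NT	NT
89	ndhF-5'-1	112345	112435	+	+	1.7,1.8,3.8	1.7,1.8,3.8
90	ndhF-5'-2	112475	112665	+	+	1.65,1.7	1.75,1.8
91	ycf5-1	114738	114982	-	NT	NT	NT
92	ycf5-2	115138	115220	-	+	.	.
93	ndhD-1	115897	116043	+	+	1.6	0.3,1.3,1.8
94	ndhD-2	116137	116437	+	+	1.3	1.35
95	ndhD-3	116467	116567	+	+	.	.
96	ndhD-4	116627	116785	+	-	NT	NT
97	ndhA-3'	119774	119911	+	NT	NT	NT
98	ndhAi	120852	120948	+	+	.	0.3,0.5
99	ndhAi-2	121194	121344	+	NT	NT	NT
100	ndhA-5'	121398	121822	+	NT	NT	NT
101	ycf1.2-1	124129	124265	+	NT	NT	NT
102	ycf1.2-2	124605	124768	+	NT	NT	NT
103	ycf1.2-3	125263	125448	+	NT	NT	NT
104	ycf1.2-4	127146	127277	+	+	2.0	0.8,2.0,3.7
105	ycf1.2-5	127626	127788	+	+	.	.
106	ycf1.2-6	127788	128098	+	-	NT	NT
107	ycf1.2-7	128220	129004	+	NT	NT	NT
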