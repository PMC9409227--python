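region_no	merged_region	chromosome	start	end	length	genes	positions	upregulated
1	3	1	3453352	3483697	30345	PRDM16;ARHGEF16	downstream;in gene	0;0
2	35	1	31689438	31715640	26202	COL16A1;LOC101929444;BAI(ADGRB2)	in gene;downstream;downstream	1;0;1
3	52	1	46170382	46203757	33375	PIK3R3;LOC105378695;TSPAN1;POMGNT1;LURAP1	upstream;upstream;in gene;downstream;upstream	0;0;0;1;0
4	89	1	151536650	151553908	17258	CGN;TUFT1;MIR554	downstream;in gene;upstream	0;0;0
5	121	1	180501359	180533622	32263	ACBD6	upstream	1
6	131	1	200885778	200903119	17341	GPR25;C1orf106;MROH3P	downstream;in gene;upstream	0;1;0
7	135	1	202566931	202600283	33352	PPP1R12B;SYT2;LOC105371686;LOC105371685	in gene;downstream;upstream;upstream	0;0;0;0
8	166	1	240758392	240811761	53369	LOC100506929;RGS7;LOC105373229	upstream;in gene;upstream	0;0;0
9	208	10	72243611	72278769	35158	ANAPC16	downstream	0
10	212	10	75207300	75264014	56714	VDAC2;COMTD1	downstream;in gene	0;0
11	248	10	132395732	132422986	27254	LRRC27;PWWP2B;LOC105378568;C10orf91	downstream;in gene;downstream;upstream	0;0;0;1
12	254	11	8806999	8841147	34148	ST5;LOC102724784;RNA5SP330	in gene;downstream;upstream	0;0;0
13	259	11	12788054	12842696	54642	TEAD1	in gene	0
14	284	11	63559618	63584348	24730	RARRES3;HRASLS2;PLA2G16;LOC105369335	downstream;upstream;downstream;upstream	0;1;0;0
15	289	11	65371027	65392675	21648	TIGD3;SLC25A45	downstream;in gene	1;0
16	315	11	114280212	114309047	28835	NNMT	upstream	0
17	390	12	47811914	47836614	24700	LOC105369749	upstream	0
18	429	12	79545485	79567438	21953	PAWR	downstream	0
19	460	12	122696516	122727563	31047	HCAR2;HCAR3;HCAR1	upstream;downstream;downstream	0;0;0
20	471	13	33118131	33129383	11252	STARD13	in gene	1
21	482	13	79480690	79494906	14216	NDFIP2-AS1;NDFIP2	upstream;in gene	0;0
22	502	14	22588162	22622517	34355	DAD1;ABHD4	upstream;in gene	0;0
23	585	15	73973341	73997593	24252	STOML1;PML	in gene;upstream	0;1
24	633	16	68731540	68802326	70786	CDH1	downstream	0
25	641	16	81559343	81602113	42770	MIR6504;	in gene;upstream	0;0
26	672	17	17900207	17972359	72152	TOM1L2;LRRC48;ATPAF2	in gene;upstream;downstream	0;0;0
27	674	17	19706613	19729962	23349	SLC47A2;ALDH3A1	in gene;downstream	1;0
28	699	17	42658915	42683176	24261	HMGB3P27;TUBG2;PLEKHH3;CCR10;CNTNAP1;EZH1;MIR6780A	downstream;downstream;in gene;downstream;upstream;downstream;downstream	0;1;0;0;1;0;0
29	746	17	82096030	82108208	12178	FASN	upstream	0
30	764	18	57770620	57846982	76362	ATP8B1;LOC1 + G3305376870;RSL24D1P11	upstream;downstream;upstream	0;0;0
31	775	19	2523762	2555593	31831	LOC101929097;GNG7	upstream;in gene	0;0
32	776	19	4367944	4403867	35923	MPND;SH3GL1;CHAF1A	downstream;in gene;upstream	0;0;1
33	778	19	6719422	6747512	28090	C3;GPR108;MIR6791;TRIP10;SH2D3A	upstream;in gene;downstream;upstream;downstream	0;0;0;0;1
34	790	19	18361769	18388017	26248	PGPEP1;GDF15;MIR3189;LRRC25	downstream;upstream;upstream;downstream	0;0;0;0
35	797	19	38251595	38320090	68495	PPP1R14A;SPINT2;YIF1B;C19orf33;KCNK6	upstream;in gene;downstream;upstream;upstream	0;0;1;0;0
36	811	19	43104469	43131735	27266	PSG5;PSG2	in gene;upstream	1;1
37	817	19	46191369	46232922	41553	IGFL2;LOC105372424;LOC645553;LOC105372423;LOC105372422;IGFL1	downstream;upstream;in gene;downstream;downstream;upstream	1;0;0;0;0;0
38	840	2	26755019	26773104	18085	C2orf18(SLC35F6);CENPA	upstream;upstream	1;1
39	849	2	36476174	36505315	29141	CRIM	in gene	0
40	905	2	85237328	85298810	61482	TCF7L1;LOC102724579;LOC105374839	in gene;downstream;downstream	0;0;0
41	995	20	10653952	10675733	21781	JAG1;MIR6870;LOC105372526	in gene;upstream;upstream	1;0;0
42	998	20	19903485	19958418	54933	RIN2	in gene	0
43	1081	21	38898236	38926384	28148	LOC400867	in gene	0
44	1084	21	41751747	41787733	35986	RIPK4;MIR6814;LOC102724800;PRDM15	upstream;upstream;in gene;downstream	0;0;0;0
45	1101	22	24950104	24997098	46994	TMEM211;KIAA1671	upstream;in gene	0;0
46	1111	22	31629899	31663559	33660	SFI1;PISD;MIR7109;PRR14L	downstream;in gene;upstream;downstream	0;1;0;0
47	1121	22	37887250	37908095	20845	EIF3L;MICALL1	downstream;upstream	0;1
48	1127	22	40482368	40542411	60043	MKL1;LOC101927257;LOC105373037	in gene;upstream;upstream	1;0;0
49	1135	22	46731873	46775788	43915	CERK;LOC105373077;TBC1D22A	upstream;upstream;upstream	0;0;0
50	1155	3	37934276	37947923	13647	CTDSPL;MIR26A1	in gene;upstream	0;0
51	1189	3	123583773	123653831	70058	HACD2;MYLK-AS1	upstream;in gene	0;0
52	1207	3	153130215	153165195	34980	RAP2B	upstream	1
53	1223	3	183253290	183297852	44562	MCF2L2;B3GNT5;RNA5SP151	in gene;downstream;upstream	0;1;0
54	1237	3	197482394	197521067	38673	LOC105374308;LOC105374309;BDH1	upstream;downstream;downstream	0;0;0
55	1299	5	57681786	57700891	19105	LOC101928505	downstream	0
56	1392	6	33731250	33789203	57953	C6orf125(UQCC2);IP6K3;LEMD2;LOC105375024;MLN	upstream;upstream;downstream;upstream;downstream	1;0;1;0;0
57	1473	7	27080276	27115997	35721	HOXA1;HOTAIRM1;HOXA2;LOC105375205	upstream;in gene;downstream;upstream	1;0;0;0
58	1475	7	28034605	28067086	32481	JAZF1;LOC105375208	in gene;in gene	0;0
59	1496	7	47633320	47694065	60745	LINC01447;C7orf65	downstream;downstream	0;1
60	1555	8	22561116	22605497	44381	PPP3CC;SORBS3;LOC105379320;PDLIM2;C8orf58;CCAR2;BIN3	downstream;downstream;upstream;in gene;upstream;upstream;downstream	0;0;0;0;1;0;0
61	1634	8	140722495	140734727	12232	MIR151A	downstream	0
62	1640	8	142777613	142796025	18412	LYNX1;LY6D	upstream;upstream	0;0
63	1655	9	22079706	22119693	39987	CDKN2B-AS1	in gene	0
64	1672	9	93093990	93149539	55549	SUSD3;LOC101927993;C9orf89;NINJ1;LOC105376150	downstream;upstream;downstream;in gene;upstream	0;0;1;0;0
65	1677	9	106860435	106921639	61204	LOC105376204;ZNF462	upstream;in gene	0;0
66	1703	9	129314856	129336831	21975	C9orf106;LINC01503	downstream;upstream	0;0
67	1708	9	136533550	136579457	45907	NOTCH1;MIR4673;LOC1053763204;MIR4674;LINC01573	upstream;upstream;downstream;upstream;downstream	0;0;0;0;0
68	1709	9	136881365	136905108	23743	MAMDC4;EDF1;LOC105376326;TRAF2;MIR4479	downstream;upstream;upstream;in gene;downstream	0;0;0;1;0
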