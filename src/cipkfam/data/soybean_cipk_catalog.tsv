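name	gene_id	chromosome	start	end	gene_length_bp	aa_length	pi	mw_kd	exon_count	cds_length_bp
GmCIPK1	Glyma.01g131500	Gm01	44789012	44792912	3901	467	8.69	52.85	1	1404
GmCIPK2	Glyma.02g202900	Gm02	38802831	38805349	2519	430	9.10	48.36	1	1293
GmCIPK3	Glyma.02g217300	Gm02	40416767	40423408	6642	444	6.11	50.45	14	1335
GmCIPK4	Glyma.02g234800	Gm02	42228835	42231757	2923	463	8.85	52.87	1	1392
GmCIPK5	Glyma.02g235100	Gm02	42255452	42257724	2273	442	7.12	49.25	1	1329
GmCIPK6	Glyma.02g275900	Gm02	45882082	45889538	7457	472	8.06	53.77	13	1419
GmCIPK7	Glyma.03g036900	Gm03	4497651	4498973	1323	413	8.63	46.46	3	1242
GmCIPK8	Glyma.03g260200	Gm03	45407900	45415032	7133	440	8.45	49.93	12	1323
GmCIPK9	Glyma.04g061500	Gm04	5015260	5017719	2460	434	8.96	48.78	2	1305
GmCIPK10	Glyma.04g090500	Gm04	7961747	7967803	6057	446	6.65	50.80	14	1341
GmCIPK11	Glyma.05g158700	Gm05	35076361	35078476	2116	517	7.23	58.42	1	1554
GmCIPK12	Glyma.06g062100	Gm06	4677276	4680311	3036	453	8.51	50.60	1	1362
GmCIPK13	Glyma.06g092300	Gm06	7283361	7289264	5904	446	7.16	50.81	14	1341
GmCIPK14	Glyma.07g023500	Gm07	1804676	1807191	2516	441	9.07	50.46	1	1326
GmCIPK15	Glyma.07g051000	Gm07	4401020	4408559	7540	438	8.89	49.91	14	1317
GmCIPK16	Glyma.08g116500	Gm08	8961418	8963555	2138	528	7.24	59.71	1	1587
GmCIPK17	Glyma.08g218400	Gm08	17747795	17750917	3123	430	9.25	48.77	1	1293
GmCIPK18	Glyma.08g252100	Gm08	22112310	22118088	5779	467	9.00	53.63	10	1404
GmCIPK19	Glyma.09g079400	Gm09	8955776	8963586	7811	448	6.26	50.53	12	1347
GmCIPK20	Glyma.09g089700	Gm09	11977305	11986209	8905	462	8.94	51.70	15	1389
GmCIPK21	Glyma.09g098000	Gm09	16564068	16566202	2135	440	9.28	49.65	1	1323
GmCIPK22	Glyma.09g276600	Gm09	49206095	49207881	1787	438	6.15	48.82	1	1317
GmCIPK23	Glyma.09g277000	Gm09	49243593	49247135	3543	460	8.52	52.36	1	1383
GmCIPK24	Glyma.10g001700	Gm10	165788	167599	1812	431	8.90	48.12	1	1296
GmCIPK25	Glyma.10g179600	Gm10	41288232	41290368	2137	437	9.10	48.53	1	1314
GmCIPK26	Glyma.11g161300	Gm11	14868303	14871145	2843	462	8.77	52.46	1	1389
GmCIPK27	Glyma.11g235300	Gm11	33029240	33033627	4388	452	8.73	50.88	1	1359
GmCIPK28	Glyma.13g069500	Gm13	16957654	16960090	2437	456	6.53	46.88	2	1371
GmCIPK29	Glyma.13g119500	Gm13	23212628	23212628	5830	446	8.45	50.08	12	1341
GmCIPK30	Glyma.13g166100	Gm13	28076313	28083963	7651	446	9.01	50.82	14	1341
GmCIPK31	Glyma.13g228400	Gm13	34069476	34071724	2249	512	6.70	57.53	1	1539
GmCIPK32	Glyma.13g228500	Gm13	34080809	34082788	1980	451	9.20	51.53	1	1356
GmCIPK33	Glyma.13g370000	Gm13	45542607	45543980	1374	425	8.87	47.35	2	1278
GmCIPK34	Glyma.14g040200	Gm14	3012174	3018140	5967	462	7.65	53.00	15	1389
GmCIPK35	Glyma.14g203000	Gm14	46787303	46790554	3252	439	7.52	48.63	1	1320
GmCIPK36	Glyma.15g003400	Gm15	309074	311683	2610	461	9.05	51.77	1	1386
GmCIPK37	Glyma.15g084000	Gm15	6435171	6436213	1043	306	8.74	35.14	2	921
GmCIPK38	Glyma.15g084100	Gm15	6445126	6447384	2259	510	6.75	57.27	1	1533
GmCIPK39	Glyma.15g187400	Gm15	19503493	19511425	7933	437	7.58	49.17	12	1314
GmCIPK40	Glyma.15g203700	Gm15	26165280	26167502	2223	438	9.31	49.51	1	1317
GmCIPK41	Glyma.16g020200	Gm16	1828561	1835982	7422	438	9.05	49.86	14	1317
GmCIPK42	Glyma.17g040700	Gm17	3002793	3008282	5490	448	8.75	50.39	12	1347
GmCIPK43	Glyma.17g066300	Gm17	5105100	5109101	4002	467	8.82	52.82	15	1404
GmCIPK44	Glyma.17g074800	Gm17	5871870	5874213	2344	422	9.17	47.60	1	1269
GmCIPK45	Glyma.17g113700	Gm17	8997933	9005687	7755	446	9.06	50.83	14	1341
GmCIPK46	Glyma.18g021600	Gm18	1584996	1589570	4575	449	8.99	50.31	1	1350
GmCIPK47	Glyma.18g054600	Gm18	4749616	4752421	2806	450	6.18	50.12	2	1353
GmCIPK48	Glyma.18g055000	Gm18	4773932	4777530	3599	462	8.80	52.40	1	1389
GmCIPK49	Glyma.18g212200	Gm18	49872222	49875889	3668	462	8.85	52.65	1	1389
GmCIPK50	Glyma.18g212700	Gm18	49942123	49944169	2047	443	6.41	49.71	1	1332
GmCIPK51	Glyma.19g111300	Gm19	36555752	36557117	1366	426	7.99	48.84	3	1281
GmCIPK52	Glyma.20g210800	Gm20	44730135	43731825	1691	436	9.22	48.62	1	1311
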