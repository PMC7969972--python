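wavelength_nm	mua_oxy_cm1	mua_deoxy_cm1	mel_ext_cm1_per_mg_ml
410	917.974	803.653	13.262
411	924.408	811.714	13.1506
412	930.159	818.318	13.0405
413	934.753	824.36	12.9316
414	937.793	830.684	12.8238
415	938.899	838.079	12.7172
416	937.781	847.277	12.6118
417	934.653	857.787	12.5075
418	929.81	868.578	12.4042
419	923.542	878.739	12.3021
420	916.198	887.497	12.201
421	905.328	894.975	12.1011
422	888.273	901.809	12.0021
423	865.245	908.085	11.9042
424	836.927	913.885	11.8074
425	804.702	919.281	11.7115
426	763.529	924.975	11.6167
427	710.433	930.886	11.5228
428	652.175	936.044	11.4299
429	596.83	939.657	11.338
430	552.119	941.021	11.2471
431	516.888	940.9	11.157
432	485.537	940.547	11.0679
433	458.091	939.977	10.9797
434	434.486	939.204	10.8924
435	414.615	938.241	10.806
436	397.892	935.136	10.7205
437	383.431	928.282	10.6359
438	370.693	918.128	10.5521
439	359.182	905.231	10.4692
440	348.441	890.47	10.3871
441	338.069	872.243	10.3058
442	328.21	847.902	10.2254
443	319.227	817.213	10.1457
444	311.453	780.31	10.0669
445	305.199	737.817	9.98881
446	300.533	681.088	9.91154
447	296.878	608.391	9.83503
448	293.587	533.233	9.75928
449	290.04	468.77	9.68428
450	285.641	424.843	9.61002
451	279.985	396.027	9.53649
452	273.248	371.469	9.46369
453	265.721	350.439	9.3916
454	257.686	332.278	9.32022
455	249.405	316.403	9.24954
456	241.119	302.295	9.17955
457	233.047	289.496	9.11023
458	225.382	277.599	9.04159
459	218.296	266.242	8.97362
460	211.942	255.108	8.9063
461	206.09	244.415	8.83964
462	200.424	234.515	8.77361
463	194.956	225.325	8.70822
464	189.696	216.77	8.64345
465	184.653	208.782	8.57931
466	179.834	201.298	8.51578
467	175.246	194.261	8.45285
468	170.894	187.618	8.39052
469	166.782	181.323	8.32878
470	162.915	175.332	8.26763
471	159.205	169.546	8.20705
472	155.585	163.929	8.14705
473	152.085	158.532	8.08761
474	148.731	153.399	8.02872
475	145.546	148.569	7.97039
476	142.554	144.073	7.91261
477	139.774	139.941	7.85536
478	137.226	136.198	7.79864
479	134.927	132.867	7.74245
480	132.894	129.969	7.68679
481	131.1	127.349	7.63164
482	129.481	124.849	7.57699
483	128.003	122.489	7.52285
484	126.635	120.283	7.46921
485	125.346	118.248	7.41606
486	124.108	116.399	7.36339
487	122.892	114.749	7.31121
488	121.671	113.312	7.2595
489	120.419	112.101	7.20827
490	119.112	111.132	7.1575
491	117.709	110.296	7.10718
492	116.221	109.485	7.05733
493	114.689	108.715	7.00792
494	113.156	108.001	6.95896
495	111.662	107.358	6.91044
496	110.243	106.799	6.86235
497	108.938	106.34	6.8147
498	107.778	105.994	6.76747
499	106.8	105.775	6.72066
500	106.034	105.699	6.67426
501	105.388	105.737	6.62828
502	104.756	105.846	6.58271
503	104.15	106.022	6.53754
504	103.583	106.261	6.49277
505	103.07	106.558	6.44839
506	102.621	106.907	6.4044
507	102.25	107.306	6.3608
508	101.97	107.749	6.31759
509	101.792	108.231	6.27474
510	101.73	108.749	6.23228
511	102.002	109.491	6.19018
512	102.782	110.625	6.14845
513	104.021	112.121	6.10708
514	105.671	113.945	6.06607
515	107.687	116.068	6.02541
516	110.023	118.457	5.9851
517	112.632	121.079	5.94514
518	115.462	123.899	5.90553
519	118.456	126.876	5.86625
520	121.552	129.969	5.82731
521	125.361	133.661	5.7887
522	130.446	138.371	5.75042
523	136.661	143.946	5.71247
524	143.846	150.215	5.67484
525	151.805	156.978	5.63752
526	160.295	163.998	5.60053
527	169.014	170.996	5.56384
528	177.6	177.652	5.52747
529	185.627	183.607	5.4914
530	192.618	188.474	5.45563
531	199.134	192.535	5.42017
532	205.968	196.349	5.385
533	212.954	199.933	5.35012
534	219.903	203.311	5.31553
535	226.606	206.508	5.28123
536	232.834	209.551	5.24722
537	238.345	212.469	5.21349
538	242.886	215.295	5.18004
539	246.201	218.061	5.14686
540	248.039	220.804	5.11396
541	249.01	223.46	5.08133
542	249.853	225.959	5.04896
543	250.517	228.334	5.01686
544	250.953	230.618	4.98503
545	251.109	232.844	4.95345
546	249.502	235.083	4.92213
547	245.312	237.32	4.89106
548	239.497	239.458	4.86025
549	232.99	241.4	4.82969
550	226.657	243.046	4.79937
551	219.783	244.573	4.7693
552	211.721	246.103	4.73948
553	203.326	247.44	4.70989
554	195.357	248.387	4.68054
555	188.474	248.747	4.65142
556	181.817	248.231	4.62254
557	174.916	246.889	4.59389
558	168.846	245.034	4.56547
559	164.551	242.976	4.53727
560	162.919	241.016	4.5093
561	163.709	239.136	4.48155
562	165.947	237.128	4.45402
563	169.455	235.009	4.4267
564	174.065	232.794	4.39961
565	179.608	230.498	4.37272
566	185.905	228.138	4.34605
567	192.753	225.727	4.31959
568	199.921	223.279	4.29333
569	207.146	220.809	4.26728
570	214.133	218.33	4.24143
571	222.337	215.845	4.21579
572	232.803	213.326	4.19034
573	244.5	210.745	4.16509
574	256.217	208.074	4.14004
575	266.546	205.287	4.11518
576	273.921	202.358	4.09051
577	276.727	199.266	4.06604
578	273.677	196.099	4.04175
579	265.273	192.902	4.01765
580	252.763	189.588	3.99373
581	237.455	186.077	3.97
582	220.603	182.294	3.94644
583	203.318	178.171	3.92307
584	186.517	173.65	3.89988
585	170.904	168.682	3.87686
586	154.33	162.339	3.85402
587	135.915	154.407	3.83135
588	117.713	145.844	3.80885
589	101.144	137.475	3.78652
590	87.0119	129.969	3.76436
591	74.5055	123.166	3.74237
592	62.9139	116.568	3.72054
593	52.6218	110.23	3.69888
594	43.7935	104.195	3.67738
595	36.4318	98.4934	3.65604
596	30.4368	93.15	3.63486
597	25.6564	88.1804	3.61384
598	21.9234	83.5941	3.59297
599	19.0792	79.3952	3.57226
600	16.9895	75.584	3.5517
601	15.3848	72.0997	3.53129
602	14.0311	68.8638	3.51104
603	12.8795	65.8502	3.49093
604	11.8916	63.0358	3.47098
605	11.0367	60.3999	3.45117
606	10.2899	57.9239	3.4315
607	9.63119	55.591	3.41198
608	9.04397	53.3862	3.3926
609	8.51466	51.2961	3.37337
610	8.03197	49.3087	3.35427
611	7.59678	47.3982	3.33532
612	7.2099	45.5552	3.3165
613	6.86254	43.7913	3.29782
614	6.54727	42.1159	3.27927
615	6.25778	40.5367	3.26086
616	5.98864	39.0598	3.24258
617	5.73518	37.6901	3.22443
618	5.49339	36.4315	3.20641
619	5.25982	35.2871	3.18853
620	5.03157	34.2595	3.17077
621	4.80885	33.3263	3.15314
622	4.59442	32.459	3.13563
623	4.38932	31.6509	3.11825
624	4.19434	30.8958	3.10099
625	4.01011	30.1881	3.08386
626	3.83707	29.5228	3.06685
627	3.67551	28.8951	3.04996
628	3.52561	28.3006	3.03319
629	3.38748	27.7353	3.01653
630	3.26113	27.1955	3
631	3.14321	26.6829	2.98358
632	3.03072	26.1994	2.96728
633	2.92409	25.7415	2.95109
634	2.82368	25.3058	2.93502
635	2.72976	24.8892	2.91906
636	2.64256	24.4889	2.90321
637	2.56225	24.1022	2.88747
638	2.48898	23.7264	2.87184
639	2.42288	23.3592	2.85632
640	2.36404	22.9982	2.84091
641	2.31122	22.6448	2.8256
642	2.26267	22.3014	2.8104
643	2.21781	21.9676	2.79531
644	2.17615	21.6433	2.78032
645	2.1372	21.3281	2.76543
646	2.10052	21.0218	2.75065
647	2.0657	20.7241	2.73597
648	2.03235	20.4348	2.72139
649	2.00011	20.1537	2.7069
650	1.96864	19.8804	2.69252
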