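designation	singletons_total	size_nt	e_score	query_coverage_pct	identity_pct	best_hit_species	SAL_1	SAL_2	SAL_3	SAL_4	genome_type	virus_family
Contig_29	21294	9030	0	57	67	Israeli acute paralysis virus	274	10312	4312	6396	ssRNA	Dicistroviridae
Contig_66	13980	2626	2E-154	76	39	Aphid lethal paralysis virus	3823	1704	5241	3212	ssRNA	Dicistroviridae
Contig_30	6197	1869	1E-139	96	40	Aphid lethal paralysis virus	2165	779	1833	1420	ssRNA	Dicistroviridae
Contig_16	2104	2371	0	83	48	Solenopsis invicta virus 1	2	133	1815	154	ssRNA	Dicistroviridae
Contig_70	641	1068	6E-64	82	43	Alber virus	117	180	141	203	RNA	Unclassified
Contig_58	607	1453	1E-67	88	34	Nasonia vitripennis virus	18	311	37	241	RNA	Unclassified
Contig_13	510	1568	2E-102	87	41	Aphid lethal paralysis virus	206	98	7	199	ssRNA	Dicistroviridae
Contig_21	486	3211	0	85	61	Acute bee paralysis virus	108	51	9	318	ssRNA	Dicistroviridae
Contig_83	428	2623	0	97	62	Mosinovirus	90	58	110	170	RNA	Unclassified
Contig_55	202	2639	3E-147	91	35	Kashmir bee virus	12	153	20	17	ssRNA	Dicistroviridae
Contig_82	114	1203	0	82	94	Acute bee paralysis virus	16	7	4	87	ssRNA	Dicistroviridae
Contig_15	100	1042	0	92	83	Hubei orthoptera virus 1	28	14	3	55	RNA	Unclassified
Contig_27	69	680	6E-135	91	97	Acute bee paralysis virus	1	6	2	60	ssRNA	Dicistroviridae
Contig_17	58	796	4E-162	99	91	Acute bee paralysis virus	15	7	5	31	ssRNA	Dicistroviridae
Contig_80	55	1173	0	98	79	Drosophila C virus	44	4	3	4	ssRNA	Dicistroviridae
Contig_75	36	589	6E-26	83	39	Hubei picorna-like virus 46	8	13	15	0	RNA	Unclassified
Contig_47	734	1045	7E-82	89	44	Solenopsis invicta virus 2	0	667	6	61	ssRNA	Unclassified
Contig_78	216	702	7E-111	99	85	Israeli acute paralysis virus	153	42	21	0	ssRNA	Dicistroviridae
Contig_57	146	1028	5E-116	93	57	Wuhan insect virus 11	0	93	28	25	RNA	Unclassified
Contig_18	44	664	2E-84	97	60	Hubei Orthoptera virus 1	10	2	0	32	RNA	Unclassified
Contig_88	44	1500	0	99	87	Rhopalosiphum padi virus	12	0	7	25	ssRNA	Dicistroviridae
Contig_53	39	522	1E-50	98	52	Wuhan insect virus 11	0	27	3	9	RNA	Unclassified
Contig_9	9	471	3E-68	87	95	Acute bee paralysis virus	3	0	3	3	ssRNA	Dicistroviridae
Contig_85	8	542	2E-53	91	56	Solenopsis invicta virus 1	4	1	3	0	ssRNA	Dicistroviridae
Contig_51	321	1465	0	99	76	Nodamura virus	0	274	0	47	ssRNA	Nodaviridae
Contig_49	182	1269	0	99	95	Aphid lethal paralysis virus	0	153	29	0	ssRNA	Dicistroviridae
Contig_12	95	438	2E-79	99	77	Big Sioux River virus	49	0	0	46	ssRNA	Unclassified
Contig_50	69	768	9E-68	99	46	Israeli acute paralysis virus	0	68	0	1	ssRNA	Dicistroviridae
Contig_60	69	926	0	99	93	Aphid lethal paralysis virus	0	55	14	0	ssRNA	Dicistroviridae
Contig_28	67	830	1E-46	97	37	Israeli acute paralysis virus	0	0	13	54	ssRNA	Dicistroviridae
Contig_52	66	356	1E-35	99	94	Shuangao insect virus 8	0	20	0	46	RNA	Unclassified
Contig_25	58	869	8E-10	37	40	Hubei picorna-like virus 50	0	0	20	38	RNA	Unclassified
Contig_141_3101	3101	2351	0	97	55	Solenopsis invicta virus 1	0	0	0	3101	ssRNA	Dicistroviridae
Contig_19	1075	1080	2E-159	89	71	Solenopsis invicta virus 1	0	0	0	1075	ssRNA	Dicistroviridae
Contig_19_480	480	623	8E-114	99	88	Solenopsis invicta virus 1	0	0	480	0	ssRNA	Dicistroviridae
Contig_110_361	361	1214	0	99	82	Kashmir bee virus	0	0	0	361	ssRNA	Dicistroviridae
Contig_81_84	84	1103	6E-161	99	67	Wuhan arthropod virus 2	0	0	84	0	RNA	Unclassified
Contig_108_79	79	715	5E-131	98	83	Shuangao insect virus 8	0	79	0	0	RNA	Unclassified
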