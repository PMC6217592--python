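term_id	name	pop_hits	microarray_count	microarray_fe	rnaseq_count	rnaseq_fe	temposeq_count	temposeq_fe
GO:0001666	Response to hypoxia	270	119	1.55	99	1.59	39	2.28
GO:0001731	Formation of translation preinitiation complex	24	17	2.50	18	3.24	9	5.92
GO:0001889	Liver development	145	85	2.07	81	2.42	32	3.48
GO:0006413	Translational initiation	52	32	2.17	29	2.41	13	3.95
GO:0006446	Regulation of translational initiation	31	19	2.16	17	2.37	12	6.11
GO:0006457	Protein folding	112	57	1.79	49	1.89	17	2.40
GO:0006629	Lipid metabolic process	89	44	1.74	42	2.04	17	3.01
GO:0006631	Fatty acid metabolic process	60	33	1.94	32	2.31	12	3.16
GO:0006635	Fatty acid beta-oxidation	46	35	2.68	31	2.92	23	7.89
GO:0006637	Acyl-coa metabolic process	28	19	2.39	16	2.47	9	5.07
GO:0006695	Cholesterol biosynthetic process	26	17	2.30	17	2.83	8	4.86
GO:0006749	Glutathione metabolic process	52	31	2.10	28	2.33	11	3.34
GO:0006915	Apoptotic process	366	157	1.51	120	1.42	41	1.77
GO:0006953	Acute-phase response	38	25	2.32	19	2.16	9	3.74
GO:0006979	Response to oxidative stress	146	76	1.83	61	1.81	22	2.38
GO:0007568	Aging	315	150	1.68	125	1.72	51	2.56
GO:0007584	Response to nutrient	137	69	1.77	59	1.86	19	2.19
GO:0007623	Circadian rhythm	121	52	1.51	46	1.64	18	2.35
GO:0009636	Response to toxic substance	119	65	1.92	61	2.22	30	3.98
GO:0009749	Response to glucose	106	54	1.80	47	1.92	18	2.68
GO:0010033	Response to organic substance	152	72	1.67	69	1.96	32	3.32
GO:0010243	Response to organonitrogen compound	68	35	1.81	34	2.16	14	3.25
GO:0014070	Response to organic cyclic compound	272	138	1.79	128	2.04	50	2.90
GO:0031100	Organ regeneration	91	45	1.74	39	1.85	22	3.82
GO:0031667	Response to nutrient levels	112	49	1.54	42	1.62	22	3.10
GO:0032355	Response to estradiol	201	91	1.60	81	1.74	40	3.14
GO:0032496	Response to lipopolysaccharide	280	114	1.43	101	1.56	39	2.20
GO:0032869	Cellular response to insulin stimulus	123	66	1.89	56	1.97	26	3.34
GO:0033539	Fatty acid beta-oxidation using acyl-coa dehydrogenase	19	16	2.97	15	3.42	9	7.48
GO:0042493	Response to drug	528	246	1.64	211	1.73	82	2.45
GO:0042542	Response to hydrogen peroxide	78	40	1.81	31	1.72	14	2.83
GO:0043065	Positive regulation of apoptotic process	338	133	1.39	115	1.47	53	2.47
GO:0043066	Negative regulation of apoptotic process	517	203	1.38	177	1.48	60	1.83
GO:0043434	Response to peptide hormone	129	63	1.72	51	1.71	19	2.32
GO:0045471	Response to ethanol	193	82	1.50	74	1.66	34	2.78
GO:0046686	Response to cadmium ion	45	27	2.11	22	2.12	12	4.21
GO:0051289	Protein homotetramerization	76	37	1.72	34	1.94	20	4.15
GO:0051301	Cell division	179	83	1.63	63	1.52	27	2.38
GO:0051384	Response to glucocorticoid	133	69	1.83	56	1.82	23	2.73
GO:0051603	Proteolysis involved in cellular protein catabolic process	51	28	1.93	24	2.04	11	3.40
GO:0055088	Lipid homeostasis	42	27	2.27	24	2.47	11	4.13
GO:0055114	Oxidation-reduction process	651	314	1.70	262	1.74	88	2.13
GO:0070542	Response to fatty acid	39	26	2.35	25	2.77	11	4.45
GO:0071407	Cellular response to organic cyclic compound	122	53	1.53	48	1.70	22	2.85
GO:0071456	Cellular response to hypoxia	137	57	1.47	49	1.55	22	2.53
GO:0097421	Liver regeneration	55	41	2.63	30	2.36	14	4.02
GO:0098609	Cell-cell adhesion	211	102	1.70	82	1.68	27	2.02
GO:1904871	Positive regulation of protein localization to Cajal body	8	8	3.52	8	4.33	6	11.84
GO:1904874	Positive regulation of telomerase RNA localization to Cajal body	15	13	3.05	12	3.46	8	8.42
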