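# Species-level percent abundance profiles of a simulated human-gut community
# (50 species): reference estimate from full-length 16S genes, estimates from
# 10,000 paired-end fragments targeting V1+V4 and V1+V5, and the weighted
# consensus of 5,000 V1+V4 + 5,000 V1+V5 fragments.
species	full_length	v1_v4	v1_v5	combined
Faecalibacterium prausnitzii	11.17	12.24	12.25	11.06
Bacteroides faecis	10.69	11.97	11.24	11.36
Prevotella amnii	6.73	0.00	6.72	7.28
Prevotella nigrescens	6.47	6.98	6.76	6.96
Megamonas hypermegale	5.35	6.06	3.53	4.71
Bacteroides pyogenes	4.23	4.44	4.33	4.55
Bacteroides finegoldii	3.98	4.03	4.13	4.00
Alistipes putredinis	3.45	3.73	3.71	3.51
Roseburia hominis	2.41	2.70	2.84	2.62
Bacteroides nordii	2.18	2.50	2.26	2.16
Bacteroides eggerthii	2.15	2.51	2.24	2.15
Bacteroides helcogenes	2.09	2.35	2.13	2.11
Bacteroides caccae	2.08	2.30	2.32	2.32
Bacteroides massiliensis	2.07	2.10	2.13	2.03
Bacteroides coprocola	2.04	2.43	2.27	2.21
Bacteroides salyersiae	2.04	2.26	2.01	2.12
Bacteroides stercoris	2.03	1.92	2.50	2.17
Bacteroides uniformis	2.02	2.03	2.04	1.93
Bacteroides acidifaciens	2.01	2.30	2.00	2.08
Proteiniphilum acetatigenes	2.01	2.21	2.18	2.07
Bacteroides cellulosilyticus	1.98	2.16	0.00	1.70
Bacteroides intestinalis	1.96	2.02	2.08	2.03
Roseburia faecis	1.74	1.94	1.91	1.69
Roseburia intestinalis	1.74	2.16	1.91	1.86
Parasutterella secunda	1.50	1.74	1.56	1.38
Roseburia inulinivorans	1.00	1.00	1.06	1.11
Phascolarctobacterium succinatutens YIT 12067	0.99	0.82	0.78	0.80
Parabacteroides distasonis	0.90	1.03	1.04	0.74
Parabacteroides merdae	0.89	1.07	0.87	0.92
Parasutterella excrementihominis	0.82	0.99	0.84	0.75
Dorea longicatena	0.78	0.32	0.51	0.32
Phascolarctobacterium faecium	0.74	0.81	0.83	0.69
Blautia producta	0.70	0.55	0.86	0.61
Escherichia/Shigella fergusonii	0.69	0.59	0.00	0.00
Escherichia/Shigella albertii	0.57	0.56	0.62	0.71
Escherichia/Shigella flexneri	0.56	0.00	0.00	0.00
Escherichia/Shigella dysenteriae	0.53	0.50	0.54	0.57
Dialister invisus	0.47	0.58	0.50	0.46
Megasphaera elsdenii	0.46	0.37	0.47	0.40
Blautia glucerasea	0.45	0.41	0.48	0.61
Blautia hydrogenotrophica	0.43	0.44	0.46	0.51
Blautia schinkii	0.43	0.47	0.54	0.43
Mitsuokella jalaludinii	0.39	0.40	0.42	0.35
Collinsella aerofaciens	0.34	0.37	0.42	0.36
Bifidobacterium longum	0.32	0.40	0.37	0.38
Bifidobacterium animalis	0.32	0.25	0.32	0.29
Ruminococcus flavefaciens	0.30	0.21	0.25	0.17
Blautia hansenii	0.28	0.33	0.30	0.33
Megasphaera sp. NMBHI-10	0.28	0.22	0.19	0.17
Klebsiella pneumoniae	0.25	0.21	0.29	0.27
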