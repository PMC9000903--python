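feature	rna_class	asd_1	ctrl_1	log2fc_1	fisher_p_1	asd_2	ctrl_2	log2fc_2	fisher_p_2
hsa-miR-10b-5p	miRNA	27.1	79.7	-1.52	2.9e-7	0.0	29.7	-4.94	2.0e-9
hsa-mir-192	miRNA	33.2	94.1	-1.48	5.7e-8	0.3	8.0	-2.77	7.8e-3
hsa-miR-22-3p	miRNA	11.3	28.7	-1.26	6.4e-3	0.0	7.2	-3.04	1.6e-2
hsa-miR-192-5p	miRNA	90.8	185.4	-1.02	1.6e-8	0.0	20.8	-4.45	9.5e-7
hsa-miR-6760-5p	miRNA	7.9	0.9	2.22	3.9e-2	11.4	0.0	3.63	9.8e-4
hsa-miR-6766	miRNA	23.6	1.8	3.14	1.0e-5	27.0	0.0	4.81	1.5e-8
hsa-miR-6839	miRNA	7.9	0.0	3.15	7.8e-3	113.3	0.0	6.84	0.0
hsa-miR-3976	miRNA	14.8	0.0	3.99	6.1e-5	36.1	14.4	1.27	2.6e-3
hsa-piR-28021	piRNA	0.0	429.1	-8.75	0.0	0.3	57.7	-5.47	0.0
hsa-piR-8876	piRNA	0.0	46.6	-5.57	0.0	0.0	9.6	-3.41	2.0e-3
hsa-piR-12132	piRNA	0.0	43.9	-5.49	0.0	14.3	804.0	-5.72	0.0
hsa-piR-32989	piRNA	0.0	9.9	-3.44	2.0e-3	2.3	37.7	-3.56	1.0e-9
hsa-piR-5819	piRNA	0.0	7.2	-3.03	1.6e-2	0.7	8.8	-2.57	2.1e-2
hsa-piR-14261	piRNA	612.0	3592.7	-2.55	0.0	9.1	20.8	-1.11	4.3e-2
hsa-piR-33186	piRNA	4681.1	23105.1	-2.30	0.0	0.0	5260.6	-12.36	0.0
hsa-piR-33033	piRNA	6091.9	20508.4	-1.75	0.0	2.9	1094.1	-8.12	0.0
hsa-piR-5751	piRNA	291.6	907.4	-1.63	0.0	0.0	32.1	-5.05	0.0
hsa-piR-8213	piRNA	11.3	28.7	-1.26	6.4e-3	1.0	8.0	-2.19	3.9e-2
hsa-piR-32837	piRNA	413.8	944.1	-1.19	0.0	1.6	74.5	-4.85	0.0
hsa-piR-32914	piRNA	413.8	944.1	-1.19	0.0	1.6	74.5	-4.85	0.0
hsa-piR-28066	piRNA	1331.4	2873.5	-1.11	0.0	1.0	40.9	-4.41	0.0
hsa-piR-31090	piRNA	39.3	18.8	1.02	1.2e-2	38.4	16.8	1.14	6.4e-3
hsa-piR-32953	piRNA	534.3	253.5	1.07	0.0	588.9	8.0	6.03	0.0
hsa-piR-26659	piRNA	267.1	121.8	1.13	0.0	608.1	283.0	1.10	0.0
hsa-piR-21363	piRNA	433.9	137.0	1.66	0.0	2058.3	484.9	2.08	0.0
hsa-piR-31508	piRNA	18.3	4.5	1.82	4.3e-3	35.2	2.4	3.41	1.0e-8
hsa-piR-16407	piRNA	14.0	1.8	2.42	4.2e-3	230.8	10.4	4.34	0.0
hsa-piR-2750	piRNA	280.2	45.7	2.59	0.0	121.4	16.8	2.78	0.0
hsa-piR-30491	piRNA	68.1	8.1	2.93	0.0	157.9	55.3	1.50	0.0
hsa-piR-22093	piRNA	7.0	0.0	3.00	1.6e-2	24.7	3.2	2.61	2.7e-5
hsa-piR-18568	piRNA	7.0	0.0	3.00	1.6e-2	13.0	0.8	2.96	1.8e-3
hsa-piR-21890	piRNA	7.9	0.0	3.15	7.8e-3	27.0	4.0	2.48	3.4e-5
hsa-piR-13475	piRNA	18.3	0.9	3.35	7.6e-5	39.4	12.0	1.63	2.0e-4
hsa-piR-8932	piRNA	66.3	5.4	3.40	0.0	86.6	40.1	1.09	3.7e-5
hsa-piR-26586	piRNA	9.6	0.0	3.41	2.0e-3	10.1	0.0	3.47	2.0e-3
hsa-piR-12718	piRNA	9.6	0.0	3.41	2.0e-3	232.1	46.5	2.30	0.0
hsa-piR-33000	piRNA	9.6	0.0	3.41	2.0e-3	560.5	68.1	3.02	0.0
hsa-piR-30677	piRNA	11.3	0.0	3.63	9.8e-4	75.2	6.4	3.36	0.0
hsa-piR-33037	piRNA	14.8	0.0	3.99	6.1e-5	16.6	4.0	1.81	7.2e-3
hsa-piR-24148	piRNA	18.3	0.0	4.27	7.6e-6	44.3	0.0	5.50	0.0
hsa-piR-3308	piRNA	18.3	0.0	4.27	7.6e-6	21.2	4.0	2.15	9.1e-4
hsa-piR-2934	piRNA	73.3	2.7	4.33	0.0	197.9	56.1	1.80	0.0
hsa-piR-33019	piRNA	20.1	0.0	4.40	1.9e-6	392.3	0.0	8.62	0.0
hsa-piR-3864	piRNA	60.2	1.8	4.46	0.0	99.3	4.0	4.32	0.0
hsa-piR-25822	piRNA	22.7	0.0	4.57	2.4e-7	108.7	28.1	1.92	0.0
hsa-piR-11291	piRNA	46.3	0.9	4.64	0.0	123.0	45.7	1.41	3.0e-9
hsa-piR-4194	piRNA	48.9	0.9	4.72	0.0	59.9	24.8	1.24	1.9e-4
hsa-piR-9502	piRNA	26.2	0.0	4.77	3.0e-8	22.5	0.0	4.55	4.8e-7
hsa-piR-8096	piRNA	27.9	0.0	4.86	7.0e-9	83.0	11.2	2.78	0.0
hsa-piR-30323	piRNA	634.7	19.7	4.94	0.0	595.1	8.0	6.05	0.0
hsa-piR-32334	piRNA	34.0	0.0	5.13	0.0	15.6	0.0	4.06	3.1e-5
hsa-piR-892	piRNA	151.9	0.0	7.26	0.0	18.6	3.2	2.22	8.5e-4
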