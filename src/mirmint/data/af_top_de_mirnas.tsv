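feature	ave_expr	logfc_persAF_vs_nonAF	fdr_persAF_vs_nonAF	logfc_parAF_vs_nonAF	fdr_parAF_vs_nonAF	logfc_persAF_vs_parAF	fdr_persAF_vs_parAF
miR-486-5p	14.89	1.08	6.82E-03	0.65	0.175	0.43	0.455
miR-451a	12.24	2.18	3.76E-05	1.28	0.046	0.90	0.187
miR-144-5p	10.76	1.97	5.44E-04	1.10	0.118	0.86	0.275
miR-223-3p	9.58	1.74	3.76E-05	0.05	0.947	1.69	2.16E-04
miR-144-3p	8.93	2.29	3.76E-05	1.19	0.06	1.10	0.102
miR-16-2-3p	7.68	1.18	3.76E-05	0.62	0.066	0.56	0.123
miR-187-3p	7.61	1.21	1.95E-04	0.35	0.431	0.87	0.038
miR-208b-3p	7.4	1.27	0.023	0.46	0.53	0.81	0.263
miR-31-5p	6.67	-2.08	3.76E-05	-1.39	0.019	-0.68	0.316
miR-182-5p	6.62	2.08	3.76E-05	1.53	0.01	0.56	0.399
miR-15b-3p	5.39	1.15	6.23E-05	0.57	0.109	0.58	0.125
miR-200b-3p	4.03	-1.41	3.70E-04	-1.05	0.03	-0.36	0.541
miR-200a-3p	3.49	-1.54	1.05E-04	-1.24	0.011	-0.29	0.624
miR-196b-5p	2.73	1.89	3.76E-05	1.13	0.047	0.76	0.209
miR-18b-5p	2.57	1.03	5.26E-04	0.36	0.37	0.67	0.086
miR-223-5p	2.47	1.20	5.63E-04	-0.18	0.776	1.38	6.75E-04
miR-135b-5p	2.43	-2.41	3.76E-05	-1.54	0.019	-0.87	0.25
miR-138-5p	2.14	-1.08	1.59E-03	-0.49	0.235	-0.58	0.209
miR-548ar-5p	1.73	1.09	2.94E-03	0.71	0.118	0.38	0.492
miR-4306	1.63	1.71	4.83E-04	1.19	0.054	0.51	0.489
miR-206	1.54	1.15	1.05E-04	1.28	0	-0.13	0.803
miR-4732-3p	1.2	2.29	1.38E-04	1.70	0.026	0.59	0.513
miR-429	0.96	-1.45	1.33E-03	-1.05	0.054	-0.41	0.542
miR-3688-3p	-0.19	1.83	3.97E-05	1.11	0.054	0.71	0.252
miR-3143	-0.33	1.99	3.76E-05	0.95	0.13	1.05	0.099
miR-187-5p	-0.46	1.36	0.019	0.74	0.324	0.63	0.455
miR-4732-5p	-0.61	2.18	1.25E-04	1.42	0.054	0.75	0.367
miR-183-5p	-0.74	1.64	6.98E-03	0.78	0.34	0.86	0.316
miR-96-5p	-1.13	2.21	3.76E-05	1.38	0.047	0.82	0.266
miR-4772-3p	-1.32	1.71	4.03E-03	0.75	0.358	0.96	0.25
miR-548y	-1.57	-1.17	0.022	-1.37	0.023	0.20	0.83
miR-208b-5p	-1.73	1.79	9.83E-03	1.04	0.246	0.75	0.466
miR-4772-5p	-1.74	1.15	0.042	-0.41	0.613	1.57	0.02
miR-33b-3p	-2.13	-1.44	9.84E-03	-1.26	0.056	-0.18	0.881
miR-3177-3p	-2.53	0.42	0.561	1.27	0.046	-0.85	0.224
miR-367-3p	-2.92	-1.38	0.021	-0.65	0.369	-0.73	0.358
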