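mirna	mrna	r	fdr	mrna_logfc_persAF_vs_nonAF	mrna_fdr_persAF_vs_nonAF	validated	predicted
miR-135b-5p	PPP1R12C	-0.482	0.007	0.625	0.000	No	Yes
miR-135b-5p	COL4A3	-0.463	0.011	0.558	0.000	Yes	Yes
miR-135b-5p	RNF152	-0.403	0.036	0.784	0.000	No	Yes
miR-138-5p	F2RL3	-0.457	0.012	2.462	0.000	No	Yes
miR-138-5p	ITPRIP	-0.415	0.029	1.128	0.000	No	Yes
miR-138-5p	HEYL	-0.476	0.008	1.119	0.000	No	Yes
miR-138-5p	KIAA0355	-0.465	0.011	0.516	0.000	No	Yes
miR-138-5p	CSPG4	-0.432	0.021	0.645	0.000	Yes	No
miR-138-5p	SLC62A2	-0.402	0.036	0.510	0.000	No	Yes
miR-144-3p	PEX5L	-0.421	0.026	-1.933	0.000	Yes	No
miR-144-3p	RBM43	-0.440	0.018	-0.649	0.000	No	Yes
miR-15b-3p	MFAP3L	-0.430	0.022	-0.587	0.000	No	Yes
miR-182-5p	EIF5	-0.427	0.023	-0.404	0.000	Yes	Yes
miR-182-5p	AJUBA	-0.408	0.032	-0.631	0.000	Yes	Yes
miR-182-5p	MFAP3L	-0.421	0.026	-0.587	0.000	No	Yes
miR-18b-5p	PARD6B	-0.421	0.026	-1.199	0.000	Yes	Yes
miR-18b-5p	AJUBA	-0.452	0.014	-0.631	0.000	Yes	No
miR-18b-5p	MFAP3L	-0.531	0.002	-0.587	0.000	Yes	No
miR-200a-3p	SCHIP1	-0.415	0.029	0.543	0.001	No	Yes
miR-200a-3p	SOX17	-0.419	0.027	1.864	0.000	No	Yes
miR-200b-3p	FLT1	-0.560	0.001	0.901	0.000	Yes	No
miR-200b-3p	PCDH19	-0.410	0.031	0.665	0.000	No	Yes
miR-206	CA12	-0.475	0.008	-2.505	0.000	No	Yes
miR-206	WWC1	-0.507	0.004	-2.345	0.000	No	Yes
miR-206	SULF1	-0.452	0.014	-0.838	0.000	No	Yes
miR-206	LIX1	-0.400	0.037	-1.765	0.003	No	Yes
miR-206	MAL2	-0.516	0.003	-1.591	0.000	No	Yes
miR-31-5p	ITPRIP	-0.493	0.005	1.128	0.000	Yes	No
miR-31-5p	CASKIN2	-0.428	0.023	0.657	0.000	Yes	No
miR-31-5p	DACT3	-0.428	0.023	0.340	0.008	Yes	No
miR-4306	PRKAB2	-0.449	0.015	-0.545	0.000	No	Yes
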