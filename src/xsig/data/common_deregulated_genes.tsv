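direction	gi	zebrafish_symbol	human_symbol	xmrk_fc	xmrk_p	kras_fc	kras_p	Myc_fc	Myc_p
up	18858688	foxa3	FOXA3	3.58	6.66E-03	1.78	4.16E-02	1.55	9.18E-03
up	18858728	gart	GART	3.32	1.42E-03	2.87	5.87E-03	7.69	6.93E-04
up	18859502	tp53	TP53	5.09	1.43E-03	1.92	1.09E-02	3.61	3.30E-03
up	41054118	c20orf24	C20orf24	4.92	2.13E-03	1.93	2.83E-03	3.14	5.22E-03
up	41393080	itm1	STT3A	1.98	7.59E-03	1.56	3.02E-02	2.01	8.07E-04
up	47086630	rhot1a	RHOT1	1.62	3.11E-02	1.87	3.00E-02	1.58	3.39E-02
up	47087206	abce1	ABCE1	4.12	1.97E-03	6.79	1.25E-02	3.01	4.40E-03
up	50344865	cdkrap3	CDK5RAP3	2.09	4.98E-03	1.85	2.06E-02	2.42	1.43E-03
up	50345019	mgat4b	MGAT4B	4.09	1.62E-02	20.55	2.92E-02	1.70	3.03E-03
up	50540209	srprb	SRPRB	1.85	2.00E-02	4.47	6.89E-04	2.65	5.84E-03
up	55742596	eif5a2	EIF5A2	4.83	1.09E-03	1.45	4.07E-03	2.98	2.14E-04
up	62955566	cirbp	CIRBP	6.11	1.63E-03	2.00	3.17E-02	2.16	1.44E-02
up	66773145	noc4l	NOC4L	2.67	4.20E-02	1.63	3.58E-02	4.34	1.05E-02
up	71834591	reep2	REEP2	4.38	3.51E-02	7.17	3.26E-03	8.38	7.95E-03
up	76253887	srp14	SRP14	4.17	1.62E-03	1.71	1.61E-02	1.91	1.15E-04
up	94536632	stmn1a	STMN1	13.83	2.30E-03	3.05	4.93E-03	4.30	1.56E-02
up	113679133	mrps9	MRPS9	1.71	2.85E-02	1.56	3.71E-02	2.40	1.59E-02
up	121583749	hmgcra	HMGCR	7.42	5.42E-03	30.45	7.30E-04	8.71	2.41E-03
up	126723627	ubap2	UBAP2	1.94	3.33E-02	1.88	4.99E-03	1.58	9.64E-03
up	148225559	fam162a	FAM162A	2.15	2.76E-03	2.16	4.72E-02	1.97	2.22E-02
up	169646807	rrp9	RRP9	4.20	1.01E-02	2.99	3.32E-02	2.71	3.48E-02
down	23308680	cyp2ad2	-	4.35	1.99E-02	9.09	8.07E-03	2.94	2.73E-02
down	41053663	scp2	SCP2	5.00	9.46E-03	2.94	2.02E-02	1.96	2.17E-02
down	41055025	hsd17b3	HSD17B3	10.00	3.20E-02	100.00	7.61E-03	33.33	1.66E-02
down	41152446	hsdl2	HSDL2	3.85	4.21E-02	2.13	3.55E-02	2.56	6.38E-03
down	47085884	fbp1b	FBP1	9.09	3.91E-04	8.33	1.86E-02	2.38	2.87E-02
down	47086066	tdh	TDH	6.67	3.28E-02	2.86	1.50E-02	3.45	3.93E-02
down	47086178	itgb1b.2	ITGB1	7.14	4.19E-02	7.14	6.40E-03	4.35	3.30E-03
down	47086928	ak3l1	AK3L1	2.17	2.31E-02	10.00	1.56E-03	2.00	2.17E-02
down	54400637	ech1	ECH1	1.52	2.29E-02	2.17	3.78E-03	2.00	1.51E-02
down	55925455	gpx4a	GPX4	3.57	6.79E-03	2.27	3.32E-02	5.26	7.31E-03
down	56790261	sod1	SOD1	2.94	4.18E-02	1.85	5.32E-03	2.27	2.48E-02
down	70778900	slc27a2	SLC27A2	9.09	3.26E-02	5.00	5.13E-03	2.78	1.08E-02
down	71834285	apobl	APOB	5.26	4.21E-02	1.79	1.20E-02	1.75	1.46E-02
down	71834671	miox	MIOX	3.13	3.05E-02	9.09	8.07E-03	4.55	4.30E-02
down	121583789	nrxn1b	NRXN1	4.76	4.87E-03	1.96	2.18E-02	6.67	1.51E-02
down	148230211	slco1d1	-	3.70	6.22E-03	4.17	1.00E-04	2.70	1.11E-03
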