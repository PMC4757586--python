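mirna	rep1_log2fc	rep1_p	rep1_sig	rep2_log2fc	rep2_p	rep2_sig	locus_type	host_gene
hsa-miR-675-5p	-2.26	0.00E+00	p<0.01	-2.84	2.09E-12	p<0.01	Intron/Exon	H19
hsa-miR-125a-3p	-1.16	7.18E-03	p<0.01	-1.08	1.67E-13	p<0.01	Intergenic	
hsa-miR-148a-3p	-1.46	6.74E-12	p<0.01	-1.21	0.00E+00	p<0.01	Intergenic	
hsa-miR-18a-5p	-1.37	1.01E-07	p<0.01	-1.47	6.01E-37	p<0.01	Intron	MIR17HG
hsa-miR-92a-1-5p	-1.51	2.20E-160	p<0.01	-1.55	1.00E-61	p<0.01	Intron	MIR17HG
hsa-miR-1277-5p	-1.8	1.22E-06	p<0.01	-2.54	6.31E-21	p<0.01	Intron	WDR44
hsa-miR-20a-5p	-1.56	6.44E-65	p<0.01	-1.12	4.98E-104	p<0.01	Intron	MIR17HG
hsa-miR-210-3p	-1.06	5.45E-10	p<0.01	-1.49	5.12E-75	p<0.01	Intergenic	
hsa-miR-222-5p	-1.03	1.91E-02	p<0.05	-1.53	3.62E-32	p<0.01	Intergenic	
hsa-miR-27a-5p	-1.14	2.53E-02	p<0.05	-3.2	0.00E+00	p<0.01	Intergenic	
hsa-miR-27b-5p	-1.73	3.66E-34	p<0.01	-1.38	7.43E-202	p<0.01	Intron	C9orf3
hsa-miR-29a-5p	-1.48	5.16E-03	p<0.01	-1.16	4.15E-03	p<0.01	Intergenic	
hsa-miR-19a-3p	-2.6	7.80E-05	p<0.01	-1.32	3.74E-321	p<0.01	Intron	MIR17HG
hsa-miR-33a-5p	-1.26	1.59E-88	p<0.01	-3.01	4.51E-16	p<0.01	Intron	SREBF2
hsa-miR-3662	-3.22	9.13E-03	p<0.01	-2.15	4.24E-09	p<0.01	Intron	HBS1L
hsa-miR-7-1-3p	-1.41	5.85E-04	p<0.01	-1.07	1.60E-02	p<0.05	Intron/Exon	HNRNPK
hsa-miR-4741	-1.66	1.72E-02	p<0.05	-1.43	2.86E-27	p<0.01	Intron	RBBP8
hsa-miR-590-3p	-2.04	1.74E-04	p<0.01	-1.3	1.32E-06	p<0.01	Intron	EIF4H
hsa-miR-196a-3p	-1.77	4.93E-02	p<0.05	-3.29	5.77E-11	p<0.01	Intergenic	
hsa-miR-4521	-2.53	5.56E-40	p<0.01	-10.43	1.77E-52	p<0.01	Intergenic	
hsa-miR-1275	-3.06	1.63E-02	p<0.05	-10.08	2.42E-41	p<0.01	Intergenic	
hsa-miR-146b-5p	1.07	9.65E-20	p<0.01	1.08	4.91E-120	p<0.01	Intergenic	
hsa-miR-449b-5p	9.92	4.06E-26	p<0.01	8.5	1.02E-15	p<0.01	Intron	CDC20B
hsa-miR-449c-5p	5.65	6.24E-300	p<0.01	4.72	1.57E-209	p<0.01	Intron	CDC20B
hsa-miR-371a-5p	6.92	6.48E-04	p<0.01	6.88	1.22E-05	p<0.01	Intergenic	
hsa-miR-184	7.19	6.39E-164	p<0.01	3.32	1.63E-13	p<0.01	Intergenic	
hsa-miR-34c-5p	2.68	2.96E-19	p<0.01	9.62	4.23E-33	p<0.01	Intergenic	
hsa-miR-3661	1.55	1.14E-02	p<0.05	3.46	1.16E-111	p<0.01	Intergenic	
hsa-miR-375	7.84	9.06E-07	p<0.01	4.25	0.00E+00	p<0.01	Intergenic	
hsa-miR-4485-3p	2.91	4.24E-06	p<0.01	3.17	1.62E-135	p<0.01	Intron	MTRNR2L8
hsa-miR-1323	2.11	1.34E-03	p<0.01	6.78	2.72E-05	p<0.01	Intergenic	
hsa-miR-449a	5.35	6.38E-22	p<0.01	9.03	2.52E-22	p<0.01	Intron	CDC20B
hsa-miR-9-5p	11.05	2.98E-56	p<0.01	2.5	8.76E-17	p<0.01	Intron	C1orf61
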