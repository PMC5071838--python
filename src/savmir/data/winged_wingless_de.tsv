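mirna_id	norm_wl	norm_w	p	fc_printed	log2fc_printed	direction_printed
PC-3p-94006_17	1	21	6.66E-05	21.00	-4.39	down
sav-mir-100-p3	1	11	7.31E-03	11.00	-3.46	down
PC-3p-420630_4	1	9	1.91E-02	9.00	-3.17	down
sav-miR-277	2863	24006	0.00E+00	8.38	-3.07	down
PC-5p-113190_15	19	3	2.15E-04	6.33	2.66	up
sav-miR-996	3	13	2.37E-02	4.33	-2.12	down
sav-miR-100	3107	11992	0.00E+00	3.86	-1.95	down
sav-let-7	1895	6399	0.00E+00	3.38	-1.76	down
PC-3p-131984_11	22	8	3.83E-03	2.75	1.46	up
PC-3p-40838_47	9	21	4.80E-02	2.47	-1.30	down
sav-miR-1	337	802	5.91E-32	2.38	-1.25	down
sav-mir-3031-p5	35	16	1.95E-03	2.19	1.13	up
sav-mir-3020-p3	17	8	3.52E-02	2.13	1.09	up
PC-3p-66379_27	32	16	6.28E-03	2.00	1.00	up
sav-miR-278	1097	2118	2.06E-48	1.93	-0.95	down
sav-miR-3030	26	14	2.24E-02	1.86	0.89	up
sav-miR-210	141	253	8.49E-06	1.79	-0.84	down
PC-3p-80125_21	22	13	4.82E-02	1.76	0.82	up
PC-3p-2743_844	622	357	3.05E-25	1.74	0.80	up
sav-mir-3033-p5	33	57	4.99E-02	1.73	-0.79	down
sav-miR-92a	362	622	1.48E-10	1.72	-0.78	down
sav-mir-92a-1-p5	39	66	4.34E-02	1.69	-0.76	down
sav-mir-316-p3	205	123	1.78E-08	1.67	0.74	up
sav-miR-3041	85	54	8.15E-04	1.57	0.65	up
sav-miR-124	1541	2398	4.47E-23	1.56	-0.64	down
sav-miR-2765	545	351	9.94E-17	1.55	0.63	up
sav-miR-92b	3549	5381	6.21E-43	1.52	-0.60	down
sav-miR-3016	159	105	1.61E-05	1.51	0.60	up
sav-miR-315	2717	1857	1.06E-63	1.46	0.55	ns
sav-miR-9a	1177	1084	1.31E-06	1.09	0.12	ns
sav-miR-8	15752	14611	1.58E-66	1.08	0.11	ns
sav-miR-7	3489	3284	7.08E-14	1.06	0.09	ns
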