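name	pubchem_cid	mw	ob	dl	herbs
Mandenol	5282184	308.56	42.0	0.19	CS;EH
Stigmasterol	5280794	412.77	43.83	0.76	CS;EH
Eriodictyol	440735	288.27	71.79	0.24	EH
Truflex OBP	66540	334.5	43.74	0.24	EH
Genkwanin	5281617	284.28	37.13	0.24	EH
Naringenin	932	272.27	59.29	0.21	EH
Beta-sitosterol	222284	414.79	36.91	0.75	EH
Quercetin	5280343	302.25	46.43	0.28	EH
Herbacetin	5280544	302.25	36.07	0.27	EH
Clionasterol (gamma-sitosterol)	457801	414.79	36.91	0.75	EH
Campesterol	173183	400.76	37.58	0.71	EH
Kaempferol	5280863	286.25	41.88	0.24	EH
24-Ethylcholest-4-en-3-one	15596633	412.77	36.08	0.76	EH
Pectolinarigenin	5320438	314.31	41.17	0.3	EH
Supraene	638072	410.8	33.55	0.42	EH
Luteolin	5280445	286.25	36.16	0.25	EH
Diosmetin	5281612	300.28	31.14	0.27	EH
Coixenolide	46173943	591.08	32.4	0.43	CS
Hydrosqualene	11975273	410.8	33.55	0.42	CS
2-Monoolein	5319879	356.61	34.23	0.29	CS
Sitosterol alpha1	9548595	426.8	43.28	0.78	CS
CLR (Cholesterol)	5997	386.73	37.87	0.68	CS
Monooleoylglycerol	11451146	356.61	34.13	0.3	CS
Sitosterol (3-epi-beta-sitosterol)	12303645	414.79	36.91	0.75	CS
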