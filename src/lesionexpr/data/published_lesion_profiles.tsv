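gene	gene_name	category	helu_fc	helu_ci_low	helu_ci_high	helu_fdr	adh_dcis_fc	adh_dcis_ci_low	adh_dcis_ci_high	adh_dcis_fdr
EGF	Epidermal growth factor	common	-4.17	ND	ND	0.019	-1.04	-1.71	-0.37	0.034
ELF5	E-74-like factor 5	common	-2.46	-3.60	-1.31	0.058	-1.88	-2.75	-1.00	0.005
FOXC1	Forkhead box C1	common	-2.69	-3.63	-1.76	0.023	-0.95	-1.38	-0.51	0.004
JAG2	Jagged 2	common	-0.53	-0.82	-0.23	0.078	-0.92	-1.37	-0.48	0.006
SOX10	SRY (sex determining region Y)-box 10	common	-1.16	-1.69	-0.64	0.058	-1.38	-1.92	-0.85	0.001
ABCG2	ATP-binding cassette, sub-family G, member 2	helu_only	-2.84	-4.28	-1.39	0.073	-0.62	-1.20	-0.04	0.149
CDC42	Cell division cycle 42	helu_only	0.66	0.25	1.07	0.091	0.99	-0.12	0.31	0.914
CLDN10	Claudin 10	helu_only	-2.70	-4.52	-1.06	0.091	0.33	-0.26	0.93	0.864
EPCAM	Epithelial cell adhesion molecule	helu_only	0.88	0.60	1.17	0.019	0.14	-0.42	0.69	0.928
EZH1	Enhancer of zeste homolog 1	helu_only	-0.74	-1.12	-0.35	0.073	0.12	-0.35	0.58	0.928
FOXA1	Forkhead box A1	helu_only	2.03	1.05	3.00	0.064	0.48	-0.28	1.25	0.855
HOXB2	Homeobox B2	helu_only	1.83	1.40	2.26	0.008	-0.07	-0.72	0.58	0.959
HOXC10	Homeobox C10	helu_only	1.09	ND	ND	0.091	0.22	-0.30	0.74	0.914
HOXC11	Homeobox C11	helu_only	3.03	1.22	4.84	0.091	0.13	-0.15	0.42	0.913
IL7R	Interleukin 7 receptor	helu_only	-2.33	-3.75	-0.90	0.091	0.23	-0.38	0.84	0.914
ITGA6	Integrin, alpha 6	helu_only	-0.85	-1.28	-0.41	0.073	-0.27	-1.15	0.60	0.914
ITGB1	Integrin, beta 1	helu_only	-0.82	-1.17	-0.48	0.049	0.58	0.12	1.04	0.830
ITGB4	Integrin, beta 4	helu_only	-0.81	-1.23	-0.38	0.073	-0.02	-0.34	0.30	0.960
MFGE8	Milk fat globule-EGF factor 8	helu_only	-1.19	-1.87	-0.52	0.078	-0.20	-0.60	0.20	0.899
MLL4	Myeloid/lymphoid or mixed-lineage leukemia 4	helu_only	-0.61	-0.99	-0.22	0.092	0.04	-0.60	0.68	0.960
MYC	v-Myc myelocytomatosis viral oncogene homolog (avian)	helu_only	-2.85	-4.46	-1.24	0.078	-0.45	-1.19	0.28	0.855
NOTCH3	Notch homolog 3	helu_only	-0.49	-0.76	-0.23	0.077	0.04	-0.22	0.30	0.959
PGR	Progesterone receptor	helu_only	2.46	1.49	3.42	0.038	0.13	-1.21	1.46	0.959
PROM1	Prominin 1	helu_only	-3.17	-4.98	-1.36	0.078	-0.78	-1.96	0.40	0.849
SMARCA4	SWI/SNF-related, matrix-associated, actin-dependent regulator of chromatin, subfamily a, member 4	helu_only	-0.77	-1.21	-0.34	0.078	0.11	-0.20	0.42	0.914
SOX9	SRY (sex determining region Y)-box 9	helu_only	-2.45	-3.58	-1.31	0.058	-0.26	-1.01	0.49	0.914
TGFA	Transforming growth factor, alpha	helu_only	-1.50	-2.41	-0.58	0.091	-0.08	-0.42	0.25	0.928
TGFB2	Transforming growth factor, beta 2	helu_only	-1.04	ND	ND	0.092	-0.14	-0.71	0.42	0.928
ACTA2	Actin, alpha 2	adh_dcis_only	-0.32	-0.71	0.06	0.353	-2.25	-2.95	-1.55	0.0001
AKT1	v-Akt murine thymoma viral oncogene homolog 1	adh_dcis_only	0.21	-0.65	1.08	0.798	1.07	0.41	1.72	0.029
CBX8	Chromobox homolog 8	adh_dcis_only	-0.82	-1.55	-0.08	0.207	-0.97	-1.58	-0.37	0.029
CD24	CD24 molecule	adh_dcis_only	0.29	-0.89	1.46	0.799	0.65	0.34	0.95	0.006
CLDN7	Claudin 7	adh_dcis_only	0.24	ND	ND	0.789	0.49	0.17	0.82	0.036
EGFR	Epidermal growth factor receptor	adh_dcis_only	-0.65	-1.20	-0.09	0.184	-0.62	-0.90	-0.34	0.004
EZH2	Enhancer of zeste homolog 2	adh_dcis_only	0.90	-0.31	2.12	0.412	1.61	0.87	2.34	0.004
GATA3	GATA-binding protein 3	adh_dcis_only	1.12	ND	ND	0.136	0.95	0.47	1.43	0.008
HOXA4	Homeobox A4	adh_dcis_only	-1.13	-1.92	-0.35	0.123	-0.64	-1.05	-0.22	0.036
HOXA5	Homeobox A5	adh_dcis_only	-1.40	-2.61	-0.18	0.189	-1.93	-2.50	-1.35	0.0001
HOXA7	Homeobox A7	adh_dcis_only	-1.54	-2.78	-0.29	0.174	-0.77	-1.14	-0.40	0.006
HOXA9	Homeobox A9	adh_dcis_only	NA	NA	NA	NA	-3.31	-4.66	-0.96	0.002
HOXB6	Homeobox B6	adh_dcis_only	0.74	ND	ND	0.685	0.92	0.32	1.52	0.075
ID2	Inhibitor of DNA-binding 2	adh_dcis_only	-0.34	-1.31	0.64	0.699	0.59	0.21	0.96	0.063
JAM2	Junctional adhesion molecule 2	adh_dcis_only	-0.62	-2.06	0.82	0.638	-0.91	-1.32	-0.49	0.004
JAM3	Junctional adhesion molecule 3	adh_dcis_only	-0.55	-1.58	0.49	0.566	-1.09	-1.50	-0.68	0.001
KRT17	Keratin 17	adh_dcis_only	0.06	-0.65	0.77	0.948	-1.63	-2.56	-0.71	0.013
MME	Membrane metallo-endopeptidase	adh_dcis_only	-0.44	-1.35	0.46	0.611	-4.42	-5.58	-3.25	<0.001
PDGFA	Platelet-derived growth factor receptor, alpha polypeptide	adh_dcis_only	-0.98	-1.77	-0.18	0.174	-1.28	-1.94	-0.63	0.008
SNAI2	Snail homolog 2	adh_dcis_only	-0.65	-1.58	0.29	0.439	-1.79	-2.59	-0.99	0.004
TGFBR3	Transforming growth factor receptor, beta 3	adh_dcis_only	-0.85	-1.65	-0.05	0.229	-2.02	-3.09	-0.96	0.010
TJP3	Tight junction protein 3	adh_dcis_only	-0.47	-0.99	0.04	0.294	1.13	0.51	1.76	0.013
WNT5B	Wingless-type MMTV integration site family, member 5B	adh_dcis_only	0.21	-0.86	1.27	0.864	-2.71	-3.75	-1.66	0.001
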