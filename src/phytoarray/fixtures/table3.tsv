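gene_symbol	gene_id	category	shikonin	emodin	cytopiloyne	BF
IL4	3565	cytokines	1.12	0.94	0.68	0.25
IRF1	3659	cytokines	2.01	0.87	0.78	0.27
TNFRSF11B	4982	cytokines	0.93	0.81	0.66	0.26
TNFRSF10C	8794	cytokines	1.04	0.96	0.86	0.32
CDH1	999	chemotaxis_migration	1.07	0.81	0.74	0.27
CDH12	1010	chemotaxis_migration	0.6	0.49	0.53	0.17
CCR2	1231	chemotaxis_migration	1.24	1.17	0.45	0.28
CCR3	1232	chemotaxis_migration	1.06	0.68	0.57	0.25
CCBP2	1238	chemotaxis_migration	0.98	0.83	0.69	0.22
ITGA2	3673	chemotaxis_migration	0.96	0.77	0.69	0.28
ITGB1	3688	chemotaxis_migration	0.9	1.69	0.72	0.32
CCL2	6347	chemotaxis_migration	0.7	0.7	0.29	0.7
CXCR4	7852	chemotaxis_migration	1.04	1.69	0.6	0.32
CD80	941	inflammatory_response	1.71	1.09	0.55	0.3
GATA3	2625	inflammatory_response	1.15	0.88	0.72	0.26
IL7R	3575	inflammatory_response	1.67	0.88	0.73	0.3
IL8RB	3579	inflammatory_response	0.83	0.64	0.62	0.26
ITK	3702	inflammatory_response	1.07	0.95	0.79	0.3
LIFR	3977	inflammatory_response	1	0.84	0.74	0.27
NFATC3	4775	inflammatory_response	2.07	3.11	0.67	0.32
MAP2K5	5607	inflammatory_response	1.31	1.03	0.65	0.33
PTGS2	5743	inflammatory_response	1.26	0.97	0.63	0.29
SLAMF1	6504	inflammatory_response	1.04	0.74	0.59	0.3
IGSF6	10261	inflammatory_response	0.58	0.87	0.33	0.67
NFATC2IP	84901	inflammatory_response	1.1	0.78	0.66	0.22
ANXA3	306	other	0.97	0.88	0.65	0.33
BCL2	596	other	1.05	1.19	0.87	0.29
MPO	4353	other	0.84	0.77	0.68	0.27
C1orf61	10485	other	1.19	1.02	0.7	0.31
CLEC1A	51267	other	0.8	0.69	0.6	0.25
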