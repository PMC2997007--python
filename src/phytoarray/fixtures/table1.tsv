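gene_symbol	gene_id	category	shikonin	emodin	cytopiloyne	BF
IL1B	3553	cytokines	0.32	0.35	0.59	0.59
IL4	3565	cytokines	0.25	0.2	0.92	0.81
IL13	3596	cytokines	0.36	0.33	0.6	0.71
IRF1	3659	cytokines	0.23	0.36	1.52	0.7
KITLG	4254	cytokines	0.31	0.34	1.03	0.74
TNF	7124	cytokines	0.24	0.68	0.38	0.85
TNFSF9	8744	cytokines	0.34	0.32	0.62	0.8
CDH12	1010	chemotaxis_migration	0.22	0.34	0.23	0.45
CCR2	1231	chemotaxis_migration	0.24	0.17	0.82	0.88
CCR3	1232	chemotaxis_migration	0.26	0.38	0.49	0.55
CCR4	1233	chemotaxis_migration	0.29	0.35	1.01	0.86
CCBP2	1238	chemotaxis_migration	0.28	0.48	0.44	0.56
ICAM2	3384	chemotaxis_migration	0.29	0.28	0.73	0.79
ITGAE	3682	chemotaxis_migration	0.34	0.32	0.55	0.59
CCL4	6351	chemotaxis_migration	0.3	0.64	0.49	0.87
CCL8	6355	chemotaxis_migration	0.33	0.35	1.03	0.81
CCL22	6367	chemotaxis_migration	0.27	0.28	0.72	0.64
SELL	6402	chemotaxis_migration	0.26	0.91	0.58	1.15
SELP	6403	chemotaxis_migration	0.24	0.18	0.44	0.57
CXCR4	7852	chemotaxis_migration	0.39	0.19	0.59	1.26
CD207	50489	chemotaxis_migration	0.26	0.41	0.6	0.67
CLEC4A	50856	chemotaxis_migration	0.49	0.33	0.68	0.89
CLEC1A	51267	chemotaxis_migration	0.3	0.47	0.32	0.54
CD1D	912	inflammatory_response	0.36	0.18	0.52	0.91
CD80	941	inflammatory_response	0.31	0.39	0.33	0.52
CSF3R	1441	inflammatory_response	0.49	0.33	0.69	0.82
IL2RA	3559	inflammatory_response	0.25	0.23	0.95	0.86
IL8RB	3579	inflammatory_response	0.27	0.34	0.64	0.53
LIFR	3977	inflammatory_response	0.27	0.48	0.32	0.6
MAP3K3	4215	inflammatory_response	0.3	0.27	0.78	0.73
NFATC3	4775	inflammatory_response	0.18	0.06	0.8	1.15
MAPK7	5598	inflammatory_response	0.28	0.26	1.09	0.66
PTGS1	5742	inflammatory_response	0.36	0.3	0.72	0.82
PTGS2	5743	inflammatory_response	0.25	0.17	1.03	0.93
SLAMF1	6504	inflammatory_response	0.33	0.58	0.37	0.67
STAT1	6772	inflammatory_response	0.29	0.2	1.04	0.8
LILRB4	11006	inflammatory_response	0.18	0.16	0.94	0.78
BCL2	596	other	0.32	0.4	0.7	0.65
BCL2L1	598	other	0.31	0.31	0.98	0.61
ETS1	2113	other	0.35	0.17	0.91	0.84
FUT7	2529	other	0.35	0.32	0.78	0.57
NR3C2	4306	other	0.33	0.48	0.89	0.66
NGFR	4804	other	0.32	0.34	0.73	0.68
TAP2	6891	other	0.2	0.14	0.72	0.85
TFRC	7037	other	0.29	0.37	1.01	0.72
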