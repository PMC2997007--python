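gene_symbol	gene_id	category	shikonin	emodin	cytopiloyne	BF
CSF1	1435	cytokines	0.91	1.69	3.54	3.12
IL5	3567	cytokines	0.87	1.35	2.77	3.01
TNFSF14	8740	cytokines	1.01	1.36	2.67	3.03
CCR1	1230	chemotaxis_migration	0.87	1.3	2.91	3.09
CCR8	1237	chemotaxis_migration	0.78	1.48	2.76	3.14
ITGAX	3687	chemotaxis_migration	1.08	1.38	2.88	3.19
CXCR4	7852	chemotaxis_migration	1.21	1.63	3.33	2.63
MADCAM1	8174	chemotaxis_migration	0.82	1.45	3.04	3.39
CD14	929	inflammatory_response	0.9	1.56	3.24	3.26
MAP2K4	6416	inflammatory_response	1.25	1.4	2.59	3.56
TLR3	7098	inflammatory_response	0.91	1.33	2.35	3.06
IL1R2	7850	inflammatory_response	0.91	1.49	2.64	3.13
TNFRSF10D	8793	inflammatory_response	0.84	1.4	2.86	3.28
TBX21	30009	inflammatory_response	0.66	1.34	2.89	3.2
SHC1	6464	other	0.89	1.22	2.4	3.2
ADAMDEC1	27299	other	1.14	1.79	2.71	3
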