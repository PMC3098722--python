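target	src_min	src_max	src_mean	mrc_score	mrc_rank	ideal
ACE_HUMAN	0.52	0.59	0.55	0.66	0.66	0.99
ACES_TORCA	0.43	0.73	0.55	0.67	0.63	0.99
ADA_BOVIN	0.20	0.39	0.28	0.15	0.17	0.99
ALDR_HUMAN	0.47	0.72	0.57	0.79	0.80	0.99
AMPC_COLI	0.28	0.59	0.45	0.47	0.44	0.98
ANDR_HUMAN	0.34	0.74	0.61	0.74	0.75	0.99
CDK2_HUMAN	0.52	0.81	0.65	0.82	0.81	0.99
COMT_RAT	0.51	0.58	0.54	0.54	0.55	0.99
DHFR_HUMAN	0.74	0.88	0.79	0.90	0.92	0.99
EGFR_HUMAN	0.41	0.65	0.51	0.54	0.65	0.99
ESR1_AG_HUMAN	0.71	0.82	0.76	0.82	0.82	0.99
ESR1_ANT_HUMAN	0.35	0.53	0.44	0.43	0.43	0.99
F10A_HUMAN	0.48	0.86	0.66	0.81	0.80	0.98
FGFR1_HUMAN	0.36	0.58	0.43	0.55	0.58	0.99
GCR_HUMAN	0.25	0.62	0.42	0.45	0.54	0.99
HMDH_HUMAN	0.60	0.77	0.65	0.58	0.61	0.99
HS9A_HUMAN	0.28	0.62	0.44	0.41	0.49	0.99
INHA_MYCTU	0.35	0.66	0.52	0.63	0.58	0.99
KITH_HHV11	0.40	0.75	0.6	0.74	0.72	0.99
MCR_HUMAN	0.80	0.87	0.85	0.82	0.84	0.99
MK14_MOUSE	0.28	0.70	0.47	0.61	0.62	0.99
NRAM_INBBE	0.79	0.90	0.85	0.88	0.86	0.99
PARP1_CHICK	0.67	0.79	0.73	0.83	0.83	0.99
PDE5A_HUMAN	0.65	0.84	0.77	0.77	0.77	0.99
PGH1_SHEEP	0.70	0.70	0.70	0.73	0.75	0.99
PGH2_MOUSE	0.58	0.75	0.67	0.71	0.69	0.99
PNPH_BOVIN	0.46	0.79	0.60	0.77	0.80	0.99
POL_HV1RT	0.46	0.68	0.61	0.72	0.76	0.99
PRGR_HUMAN	0.61	0.72	0.65	0.71	0.84	0.99
PUR3_COLI	0.80	0.88	0.85	0.85	0.94	0.99
PYGM_RABIT	0.21	0.44	0.32	0.22	0.26	0.99
RXRA_HUMAN	0.50	0.93	0.76	0.88	0.85	0.98
SRC_HUMAN	0.38	0.63	0.52	0.61	0.60	0.99
THRB_HUMAN	0.28	0.63	0.47	0.50	0.50	0.99
TRY1_BOVIN	0.33	0.89	0.69	0.76	0.79	0.99
VGFR2_HUMAN	0.45	0.62	0.55	0.70	0.73	0.99
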