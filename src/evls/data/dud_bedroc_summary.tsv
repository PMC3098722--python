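target	src_min	src_max	src_mean	mrc_score	mrc_rank	ideal
ACE_HUMAN	0.23	0.37	0.31	0.45	0.44	1
ACES_TORCA	0.01	0.37	0.10	0.25	0.17	1
ADA_BOVIN	0	0.05	0.01	0.01	0.01	1
ALDR_HUMAN	0.04	0.47	0.3	0.66	0.66	1
AMPC_COLI	0.01	0.13	0.05	0.06	0.07	1
ANDR_HUMAN	0.12	0.45	0.32	0.45	0.45	1
CDK2_HUMAN	0.10	0.51	0.27	0.40	0.41	1
COMT_RAT	0.01	0.08	0.04	0.07	0.06	1
DHFR_HUMAN	0.38	0.71	0.48	0.55	0.64	1
EGFR_HUMAN	0.09	0.4	0.23	0.21	0.36	1
ESR1_AG_HUMAN	0.40	0.51	0.47	0.54	0.54	1
ESR1_ANT_HUMAN	0.01	0.33	0.22	0.30	0.28	1
F10A_HUMAN	0.05	0.59	0.26	0.53	0.38	1
FGFR1_HUMAN	0.08	0.25	0.14	0.17	0.22	1
GCR_HUMAN	0	0.30	0.11	0.27	0.28	1
HMDH_HUMAN	0.21	0.46	0.28	0.42	0.42	1
HS9A_HUMAN	0	0.37	0.11	0.05	0.23	1
INHA_MYCTU	0.01	0.20	0.09	0.19	0.12	1
KITH_HHV11	0.01	0.23	0.14	0.22	0.22	1
MCR_HUMAN	0.54	0.76	0.67	0.62	0.68	1
MK14_MOUSE	0.01	0.31	0.09	0.22	0.18	1
NRAM_INBBE	0.37	0.72	0.56	0.61	0.46	1
PARP1_CHICK	0.36	0.47	0.42	0.44	0.44	1
PDE5A_HUMAN	0.17	0.42	0.31	0.37	0.30	1
PGH1_SHEEP	0.25	0.31	0.28	0.30	0.33	1
PGH2_MOUSE	0.06	0.28	0.17	0.22	0.17	1
PNPH_BOVIN	0.03	0.49	0.2	0.31	0.39	1
POL_HV1RT	0.09	0.38	0.24	0.36	0.43	1
PRGR_HUMAN	0.24	0.49	0.39	0.53	0.54	1
PUR3_COLI	0.50	0.61	0.57	0.60	0.77	1
PYGM_RABIT	0	0.07	0.02	0.04	0.04	1
RXRA_HUMAN	0.11	0.62	0.35	0.49	0.33	1
SRC_HUMAN	0.04	0.27	0.17	0.26	0.22	1
THRB_HUMAN	0.03	0.27	0.18	0.24	0.27	1
TRY1_BOVIN	0.02	0.39	0.19	0.21	0.23	1
VGFR2_HUMAN	0.08	0.23	0.17	0.33	0.33	1
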