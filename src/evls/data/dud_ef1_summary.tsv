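target	src_min	src_max	src_mean	mrc_score	mrc_rank	ideal
ACE_HUMAN	6.5	21.7	15.2	23.9	23.9	39.1
ACES_TORCA	0	16.1	2.2	4.0	5.0	39.0
ADA_BOVIN	0	0	0	0	0	39.1
ALDR_HUMAN	0	30.7	17.9	34.6	30.8	38.4
AMPC_COLI	0	4.7	0.6	0	4.7	38.0
ANDR_HUMAN	2.9	23.5	14.7	25.0	22.0	42.6
CDK2_HUMAN	2.1	21.2	10.3	10.6	12.7	44.6
COMT_RAT	0	0	0	0	0	36.3
DHFR_HUMAN	13.7	33.6	20.3	14.2	20.5	44.7
EGFR_HUMAN	3	16.1	9.3	9.9	14.0	43.5
ESR1_AG_HUMAN	14.3	19.0	16.2	17.4	12.7	41.2
ESR1_ANT_HUMAN	0	22.2	12.4	16.6	11.1	55.5
F10A_HUMAN	0	25.0	7.9	15.6	9.3	32.8
FGFR1_HUMAN	2.8	7.0	4.5	2.8	9.8	49.2
GCR_HUMAN	0	25.0	7.3	25.0	25.0	81.2
HMDH_HUMAN	4	36.0	17.7	20.0	24.0	56.0
HS9A_HUMAN	0	21.7	6.7	0	17.4	39.1
INHA_MYCTU	0	8.7	2.0	5.2	1.7	47.3
KITH_HHV11	0	9.1	2.6	9.1	4.5	40.1
MCR_HUMAN	30.7	46.1	39.8	38.4	30.7	46.1
MK14_MOUSE	0	13.1	3.15	11.7	7.3	50.3
NRAM_INBBE	4.1	28.6	16.9	16.3	10.2	34.7
PARP1_CHICK	3.22	16.1	8.0	9.7	6.4	41.9
PDE5A_HUMAN	3.8	23.0	11.1	15.3	11.5	65.4
PGH1_SHEEP	13	17.4	15.2	17.4	13.0	39.1
PGH2_MOUSE	0.9	3.8	2.3	2.3	2.3	36.8
PNPH_BOVIN	0	16.0	5.0	4.0	16	40.0
POL_HV1RT	2.9	20.6	10.5	11.7	14.7	44.1
PRGR_HUMAN	13.6	27.2	22.7	27.2	27.2	40.9
PUR3_COLI	12.5	12.5	12.5	12.5	12.5	12.5
PYGM_RABIT	0	3.8	0.9	1.9	1.9	40.3
RXRA_HUMAN	0	22.2	5.9	11.1	5.5	27.7
SRC_HUMAN	1.0	15.3	8.4	11.2	10.2	58.1
THRB_HUMAN	0	13.0	5.0	4.3	4.3	47.82
TRY1_BOVIN	0	11.1	2.9	0	11.1	77.7
VGFR2_HUMAN	4.1	18.7	8.1	18.7	12.5	56.2
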